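"""Deterministic and stochastic integration of the thalamocortical model.

Deterministic runs use an adaptive embedded Runge-Kutta 4(5) pair with
dense output, sampled onto a uniform grid. Stochastic runs use the
fixed-step Euler-Maruyama scheme with an additive Gaussian increment of
standard deviation ``sd * sqrt(dt)`` applied to the TC population only
(non-specific ascending input from the brain stem enters the model
through the thalamocortical relay population).

Reproducibility: every Gaussian increment stream is drawn from a PCG64
generator keyed by ``numpy.random.SeedSequence(entropy=seed,
spawn_key=indices)``, so trial streams are independent of each other
and of the order in which they are evaluated. A :class:`NoisePlan` may
carry two seeds spliced at a switch time, which is how stimulation
trials keep the pre-stimulus noise fixed while varying the
post-stimulus noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import _em
from .model import ModelParameters, Trajectory, as_state, vector_field

__all__ = [
    "DEFAULT_DT",
    "NoisePlan",
    "IntegrationError",
    "trial_seed",
    "make_increments",
    "integrate_deterministic",
    "integrate_stochastic",
    "save_trajectory",
    "load_trajectory",
]

#: Default Euler-Maruyama step size in seconds, calibrated so that the
#: noise preset (alpha = 0.022) produces spontaneous seizures of about
#: 5-10 s roughly every few minutes; see docs/methods.md.
DEFAULT_DT = 2e-4


class IntegrationError(RuntimeError):
    """Integration failed; the message names the failure time."""


def trial_seed(base_seed: int, *indices: int) -> np.random.SeedSequence:
    """Independent per-trial seed stream derived from (base_seed, indices)."""
    return np.random.SeedSequence(entropy=base_seed, spawn_key=tuple(indices))


@dataclass
class NoisePlan:
    """Recipe for a reproducible Gaussian increment sequence.

    Increment i (covering [i*dt, (i+1)*dt)) is drawn from the stream
    keyed by ``seed_pre`` if ``i*dt < switch_time``, else from
    ``seed_post``. With ``switch_time`` unset the whole run uses
    ``seed_pre``.
    """

    dt: float = DEFAULT_DT
    seed_pre: int | np.random.SeedSequence = 0
    seed_post: int | np.random.SeedSequence | None = None
    switch_time: float | None = None
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if (self.switch_time is not None) and self.seed_post is None:
            raise ValueError("switch_time given but seed_post missing")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))


def make_increments(plan: NoisePlan, n_steps: int) -> np.ndarray:
    """Gaussian increments, pre-scaled to sd * sqrt(dt), length n_steps."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    scale = plan.sd * np.sqrt(plan.dt)
    if plan.switch_time is None:
        n_pre = n_steps
    else:
        # increments with i*dt < switch_time come from the pre stream
        n_pre = min(n_steps, int(np.ceil(plan.switch_time / plan.dt - 1e-12)))
    out = np.empty(n_steps)
    out[:n_pre] = _rng(plan.seed_pre).standard_normal(n_pre)
    if n_steps > n_pre:
        out[n_pre:] = _rng(plan.seed_post).standard_normal(n_steps - n_pre)
    return out * scale


def integrate_deterministic(
    params: ModelParameters,
    x0,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    sample_rate: float = 1000.0,
) -> Trajectory:
    """Adaptive RK45 solution sampled on a uniform grid (alpha ignored)."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be > 0")
    x0 = as_state(x0)
    sol = solve_ivp(
        lambda _t, y: vector_field(y, params),
        (0.0, t_end),
        x0,
        method="RK45",
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(
            f"deterministic integration failed at t={sol.t[-1]:.6g} s: "
            f"{sol.message}"
        )
    n = int(round(t_end * sample_rate))
    times = np.arange(n + 1) / sample_rate
    states = sol.sol(times).T
    if not np.all(np.isfinite(states)):
        raise IntegrationError("non-finite state in deterministic solution")
    return Trajectory(times, states)


def integrate_stochastic(
    params: ModelParameters,
    x0,
    t_end: float,
    plan: NoisePlan,
    thin: int = 1,
) -> Trajectory:
    """Fixed-step Euler-Maruyama solution sampled every `thin` steps.

    The number of steps is rounded up to a multiple of `thin` so the
    returned grid always reaches at least t_end.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    x0 = as_state(x0)
    n_steps = int(np.ceil(round(t_end / plan.dt, 9)))
    n_steps = ((n_steps + thin - 1) // thin) * thin
    dw = make_increments(plan, n_steps)
    return _run_em(params, x0, plan.dt, dw, thin)


def _run_em(params, x0, dt, dw, thin=1) -> Trajectory:
    """Drive the EM kernel with a precomputed increment array."""
    n_steps = dw.shape[0]
    out = np.empty((n_steps // thin + 1, 4))
    fail = _em.em_path(x0, _em.pack_params(params),
                       params.thalamic_activation == "linear",
                       dt, dw, thin, out)
    if fail:
        raise IntegrationError(
            f"non-finite state at t={fail * dt:.6g} s during "
            "Euler-Maruyama integration"
        )
    times = np.arange(out.shape[0]) * (dt * thin)
    return Trajectory(times, out)


# -- serialization ------------------------------------------------------

def save_trajectory(traj: Trajectory, path, metadata: dict | None = None) -> None:
    """Binary array container (.npz) with a JSON metadata sidecar."""
    path = str(path)
    np.savez_compressed(path, times=traj.times, states=traj.states)
    if metadata is not None:
        sidecar = path + ".json" if not path.endswith(".npz") \
            else path[:-4] + ".json"
        with open(sidecar, "w") as fh:
            json.dump(metadata, fh, indent=2, default=str)


def load_trajectory(path) -> Trajectory:
    with np.load(path) as data:
        return Trajectory(data["times"], data["states"])
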
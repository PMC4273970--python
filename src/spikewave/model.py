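"""Core thalamocortical neural mass model of spike-wave discharges.

The model describes the mean activity of four coupled neural populations:
cortical pyramidal cells (PY), cortical inhibitory interneurons (IN),
thalamocortical relay cells (TC), and thalamic reticular cells (RE).
Each population relaxes towards a constant input offset plus weighted
input from the populations it is connected to:

    dPY/dt = tau_py * (h_py - PY + c1*f(PY) - c3*f(IN) + c9*f(TC))
    dIN/dt = tau_in * (h_in - IN + c2*f(PY))
    dTC/dt = tau_tc * (h_tc - TC + c7*f(PY) - c6*s(RE))
    dRE/dt = tau_re * (h_re - RE + c8*f(PY) + c5*s(TC) - c4*s(RE))

where ``f(u) = 1 / (1 + epsilon**(-u))`` is a steep sigmoid and the
thalamic subsystem uses a linear activation ``s(u) = a*u + b`` (the
thalamic populations operate in the near-linear range of the sigmoid;
``s`` can be switched back to ``f`` to check that nothing qualitative
depends on this simplification).

The slow thalamic timescales (tau_tc = tau_re = 2.6 /s against cortical
rates an order of magnitude faster) produce the characteristic
spike-and-wave morphology: parameters are set so that a stable
background equilibrium coexists with a large-amplitude spike-wave limit
cycle (bistability), and noise on TC drives spontaneous transitions
between the two.

The model EEG observable is the mean of the two cortical populations.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import optimize

__all__ = [
    "PY",
    "IN",
    "TC",
    "RE",
    "STATE_NAMES",
    "ModelParameters",
    "Trajectory",
    "FixedPointError",
    "UnstableFixedPointError",
    "state",
    "as_state",
    "sigmoid_activation",
    "linear_activation",
    "vector_field",
    "jacobian",
    "eeg_observable",
    "find_background_fixed_point",
]

# State vector component indices. A model state is a float array of
# shape (4,) ordered (PY, IN, TC, RE).
PY, IN, TC, RE = 0, 1, 2, 3
STATE_NAMES = ("py", "inh", "tc", "re")


class FixedPointError(RuntimeError):
    """Fixed point search failed to converge."""


class UnstableFixedPointError(RuntimeError):
    """A root was found but its linearization is not stable.

    Raised so a caller searching for the *background* equilibrium is
    never silently handed a saddle on the basin boundary.
    """


def state(py: float, inh: float, tc: float, re: float) -> np.ndarray:
    """Build a state vector (PY, IN, TC, RE) as a float array."""
    return np.array([py, inh, tc, re], dtype=float)


def as_state(x) -> np.ndarray:
    """Coerce to a finite 4-component float array; raise otherwise."""
    arr = np.asarray(x, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"state must have shape (4,), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite state: {arr}")
    return arr


@dataclass
class ModelParameters:
    """All model constants; defaults are the noise-driven preset.

    Two presets are provided, differing only in the TC input offset and
    the noise amplitude: :meth:`noise` (h_tc = -2.05, alpha = 0.022,
    used for the stochastic experiments) and :meth:`deterministic`
    (h_tc = -2.0, alpha = 0, used for the noise-free basin and
    stimulation scans).

    Units: tau_* are rates (1/s); h_* , a_lin/b_lin offsets and alpha
    are in the dimensionless population-activity units; c1..c9 and
    epsilon are dimensionless.
    """

    c1: float = 1.8    # PY -> PY (self-excitation)
    c2: float = 4.0    # PY -> IN
    c3: float = 1.5    # IN -> PY (inhibitory)
    c4: float = 0.2    # RE -> RE (self-inhibition)
    c5: float = 10.5   # TC -> RE
    c6: float = 0.6    # RE -> TC (inhibitory)
    c7: float = 3.0    # PY -> TC
    c8: float = 3.0    # PY -> RE
    c9: float = 1.0    # TC -> PY
    tau_py: float = 26.0
    tau_in: float = 32.5
    tau_tc: float = 2.6
    tau_re: float = 2.6
    h_py: float = -0.35
    h_in: float = -3.4
    h_tc: float = -2.05
    h_re: float = -5.0
    epsilon: float = 250000.0
    a_lin: float = 2.8
    b_lin: float = 0.5
    alpha: float = 0.022
    thalamic_activation: str = "linear"

    def __post_init__(self) -> None:
        for name in ("tau_py", "tau_in", "tau_tc", "tau_re"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.epsilon <= 1:
            raise ValueError("epsilon must be > 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.thalamic_activation not in ("linear", "sigmoid"):
            raise ValueError(
                "thalamic_activation must be 'linear' or 'sigmoid', "
                f"got {self.thalamic_activation!r}"
            )

    @classmethod
    def noise(cls, **overrides) -> "ModelParameters":
        """Stochastic preset (h_tc = -2.05, alpha = 0.022)."""
        return cls(**overrides)

    @classmethod
    def deterministic(cls, **overrides) -> "ModelParameters":
        """Noise-free preset (h_tc = -2.0, alpha = 0)."""
        kw = {"h_tc": -2.0, "alpha": 0.0}
        kw.update(overrides)
        return cls(**kw)

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    @property
    def h(self) -> np.ndarray:
        return np.array([self.h_py, self.h_in, self.h_tc, self.h_re])

    @property
    def tau(self) -> np.ndarray:
        return np.array([self.tau_py, self.tau_in, self.tau_tc, self.tau_re])

    # -- YAML round trip ------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str | io.TextIOBase) -> "ModelParameters":
        if hasattr(text, "read"):
            text = text.read()
        data = yaml.safe_load(text)
        return cls(**data)


def sigmoid_activation(u, epsilon: float):
    """Steep logistic activation ``1 / (1 + epsilon**(-u))``.

    Evaluated as a logistic in ``u * ln(epsilon)`` so that the huge
    default steepness (epsilon = 2.5e5) never overflows: the positive
    and negative branches are computed separately through a decaying
    exponential.
    """
    z = np.multiply(u, np.log(epsilon))
    # scipy.special.expit(z) == 1/(1+e^-z); use it for stability.
    from scipy.special import expit

    return expit(z)


def linear_activation(u, a: float, b: float):
    """Affine activation ``a*u + b`` used for the thalamic subsystem."""
    return a * np.asarray(u, dtype=float) + b


def _activations(x: np.ndarray, p: ModelParameters):
    """Return (f_py, f_in, f_tc, s_tc, s_re) for a state."""
    f_py = sigmoid_activation(x[PY], p.epsilon)
    f_in = sigmoid_activation(x[IN], p.epsilon)
    f_tc = sigmoid_activation(x[TC], p.epsilon)
    if p.thalamic_activation == "linear":
        s_tc = linear_activation(x[TC], p.a_lin, p.b_lin)
        s_re = linear_activation(x[RE], p.a_lin, p.b_lin)
    else:
        s_tc = sigmoid_activation(x[TC], p.epsilon)
        s_re = sigmoid_activation(x[RE], p.epsilon)
    return f_py, f_in, f_tc, s_tc, s_re


def vector_field(x, params: ModelParameters) -> np.ndarray:
    """Time derivative (per second) of the four population activities."""
    x = as_state(x)
    p = params
    f_py, f_in, f_tc, s_tc, s_re = _activations(x, p)
    return np.array(
        [
            p.tau_py * (p.h_py - x[PY] + p.c1 * f_py - p.c3 * f_in + p.c9 * f_tc),
            p.tau_in * (p.h_in - x[IN] + p.c2 * f_py),
            p.tau_tc * (p.h_tc - x[TC] + p.c7 * f_py - p.c6 * s_re),
            p.tau_re * (p.h_re - x[RE] + p.c8 * f_py + p.c5 * s_tc - p.c4 * s_re),
        ]
    )


def _sigmoid_deriv(u: float, epsilon: float) -> float:
    s = sigmoid_activation(u, epsilon)
    return float(np.log(epsilon) * s * (1.0 - s))


def jacobian(x, params: ModelParameters) -> np.ndarray:
    """Analytic 4x4 Jacobian of :func:`vector_field` (per second)."""
    x = as_state(x)
    p = params
    df_py = _sigmoid_deriv(x[PY], p.epsilon)
    df_in = _sigmoid_deriv(x[IN], p.epsilon)
    df_tc = _sigmoid_deriv(x[TC], p.epsilon)
    if p.thalamic_activation == "linear":
        ds_tc = p.a_lin
        ds_re = p.a_lin
    else:
        ds_tc = _sigmoid_deriv(x[TC], p.epsilon)
        ds_re = _sigmoid_deriv(x[RE], p.epsilon)
    J = np.zeros((4, 4))
    J[PY, PY] = p.tau_py * (-1.0 + p.c1 * df_py)
    J[PY, IN] = p.tau_py * (-p.c3 * df_in)
    J[PY, TC] = p.tau_py * (p.c9 * df_tc)
    J[IN, PY] = p.tau_in * (p.c2 * df_py)
    J[IN, IN] = -p.tau_in
    J[TC, PY] = p.tau_tc * (p.c7 * df_py)
    J[TC, TC] = -p.tau_tc
    J[TC, RE] = p.tau_tc * (-p.c6 * ds_re)
    J[RE, PY] = p.tau_re * (p.c8 * df_py)
    J[RE, TC] = p.tau_re * (p.c5 * ds_tc)
    J[RE, RE] = p.tau_re * (-1.0 - p.c4 * ds_re)
    return J


def eeg_observable(x) -> float:
    """Model EEG: mean of the two cortical population activities."""
    x = np.asarray(x, dtype=float)
    return (x[..., PY] + x[..., IN]) / 2.0 if x.ndim > 1 else (x[PY] + x[IN]) / 2.0


@dataclass
class Trajectory:
    """A uniformly sampled solution: times (s) and states (n, 4).

    The EEG observable is always derived from the states, never stored
    independently, so the invariant eeg = (PY + IN)/2 holds by
    construction.
    """

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.shape[0], 4):
            raise ValueError(
                f"states shape {self.states.shape} inconsistent with "
                f"{self.times.shape[0]} time samples"
            )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def py(self) -> np.ndarray:
        return self.states[:, PY]

    @property
    def inh(self) -> np.ndarray:
        return self.states[:, IN]

    @property
    def tc(self) -> np.ndarray:
        return self.states[:, TC]

    @property
    def re(self) -> np.ndarray:
        return self.states[:, RE]

    @property
    def eeg(self) -> np.ndarray:
        return (self.states[:, PY] + self.states[:, IN]) / 2.0

    @property
    def fs(self) -> float:
        """Sampling rate in Hz (uniform grid)."""
        return 1.0 / float(self.times[1] - self.times[0])

    def state_at(self, t: float, interpolate: bool = False) -> np.ndarray:
        """State at time t: nearest earlier sample, or linear interpolation."""
        if not (self.times[0] - 1e-12 <= t <= self.times[-1] + 1e-12):
            raise ValueError(f"t={t} outside trajectory span "
                             f"[{self.times[0]}, {self.times[-1]}]")
        if interpolate:
            return np.array(
                [np.interp(t, self.times, self.states[:, k]) for k in range(4)]
            )
        idx = int(np.searchsorted(self.times, t + 1e-12) - 1)
        return self.states[max(idx, 0)].copy()

    def window(self, t0: float, t1: float) -> "Trajectory":
        """Sub-trajectory covering [t0, t1] (inclusive of boundary samples)."""
        mask = (self.times >= t0 - 1e-12) & (self.times <= t1 + 1e-12)
        return Trajectory(self.times[mask], self.states[mask])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "py": self.py,
                "inh": self.inh,
                "tc": self.tc,
                "re": self.re,
                "eeg": self.eeg,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(),
                   df[["py", "inh", "tc", "re"]].to_numpy())


def find_background_fixed_point(
    params: ModelParameters,
    guess=None,
    tol: float = 1e-12,
    max_relaxations: int = 3,
) -> np.ndarray:
    """Locate the stable background equilibrium of the deterministic model.

    Uses a damped Powell-hybrid root search seeded at the decoupled
    equilibrium (h_py, h_in, h_tc, h_re), with a relaxation-simulation
    fallback: if the root search stalls or lands on an unstable root
    from a user-supplied guess far from the equilibrium, the state is
    relaxed along the flow for a few seconds and the search restarted.

    Raises
    ------
    FixedPointError
        if no root with ||vector_field||_inf < 1e-10 is found.
    UnstableFixedPointError
        if the converged root has an eigenvalue with non-negative real
        part (i.e. it is not the background attractor).
    """
    if guess is None:
        guess = params.h
    x = as_state(guess)

    def fun(z):
        return vector_field(z, params)

    def jac(z):
        return jacobian(z, params)

    last_root = None
    for _ in range(max_relaxations):
        sol = optimize.root(fun, x, jac=jac, method="hybr", tol=tol)
        root = sol.x
        if np.max(np.abs(fun(root))) < 1e-10:
            last_root = root
            eig = np.linalg.eigvals(jac(root))
            if np.all(eig.real < 0):
                return root
        # fallback: relax along the flow and retry
        from .integrate import integrate_deterministic

        traj = integrate_deterministic(params, x, t_end=5.0, sample_rate=100.0)
        x = traj.states[-1]
    if last_root is not None:
        raise UnstableFixedPointError(
            f"root {last_root} found but not linearly stable; "
            "the guess likely lies outside the background basin"
        )
    raise FixedPointError("fixed point search did not converge")
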
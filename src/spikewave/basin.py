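"""Basin-of-attraction reconstruction and return probabilities.

The background equilibrium's basin of attraction is reconstructed by
systematically scanning initial conditions in the 4-D state space and
classifying each trajectory as returning to background or remaining on
the spike-wave attractor. Under noise the binary membership becomes a
return probability, estimated by repeating each trial with independent
noise streams (20 by default) and taking the success fraction.

Classification contract
-----------------------
Two interchangeable rules are provided:

* ``eeg_threshold`` — background iff the EEG stays at or below a
  threshold for *every* sample of the 3-s horizon (the threshold is a
  heuristic for high-amplitude SW oscillation; default is the midpoint
  between the fixed-point EEG and the SW maximum);
* ``fp_vicinity`` — background iff the state at the end of the horizon
  lies within a small Euclidean ball around the fixed point.

A third rule expresses the termination reading of the same heuristic:

* ``sw_termination`` — background iff no EEG sample *after* the
  horizon exceeds the threshold, i.e. all super-threshold SW activity
  ceases within the horizon. This is the criterion used for the
  stimulation success-rate maps: it tolerates the relaxation tail of a
  seizure that terminates late in the window, which the two strict
  rules count as failure (the state needs ~1.5 s to decay into a
  0.1-radius ball, so vicinity-at-horizon effectively halves the
  horizon). It requires the trajectory to extend a settling margin
  beyond the horizon.

All three agree on the unambiguous cases (resting at the fixed point;
cycling on the SW attractor).

All scan trajectories are integrated with the fixed-step scheme at the
package's stochastic step size, so that deterministic (alpha = 0) scans
are the exact zero-noise limit of the probabilistic ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attractor import SEIZURE_KICK, sw_threshold
from .integrate import DEFAULT_DT, NoisePlan, integrate_stochastic, trial_seed
from .model import (
    STATE_NAMES,
    ModelParameters,
    Trajectory,
    FixedPointError,
    UnstableFixedPointError,
    eeg_observable,
    find_background_fixed_point,
)

__all__ = [
    "ClassificationRule",
    "SliceSpec",
    "BasinGrid",
    "classify_outcome",
    "estimate_return_probability",
    "scan_basin",
    "slice_along_attractor",
    "classify_attractor_regime",
    "scan_parameter_1d",
]

#: Samples per second kept when thinning fixed-step scan trajectories.
SCAN_FS = 1000.0


@dataclass
class ClassificationRule:
    """Background-vs-seizure decision over a fixed horizon."""

    mode: str = "eeg_threshold"
    eeg_threshold: float | None = None
    horizon: float = 3.0
    vicinity_radius: float = 0.1
    fixed_point: np.ndarray | None = None
    settle_margin: float = 0.4  # post-horizon window checked by sw_termination

    def __post_init__(self) -> None:
        if self.mode not in ("eeg_threshold", "fp_vicinity", "sw_termination"):
            raise ValueError(f"unknown rule mode {self.mode!r}")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if self.mode == "fp_vicinity":
            if self.vicinity_radius <= 0:
                raise ValueError("vicinity_radius must be > 0")
            if self.fixed_point is None:
                raise ValueError("fp_vicinity mode needs fixed_point")
        if self.mode in ("eeg_threshold", "sw_termination") \
                and self.eeg_threshold is None:
            raise ValueError(f"{self.mode} mode needs a threshold value")

    @property
    def span(self) -> float:
        """Post-reference trajectory length the rule needs to classify."""
        return self.horizon + (self.settle_margin
                               if self.mode == "sw_termination" else 0.0)

    @classmethod
    def for_model(
        cls,
        params: ModelParameters,
        mode: str = "eeg_threshold",
        horizon: float = 3.0,
        vicinity_radius: float = 0.1,
    ) -> "ClassificationRule":
        """Build a rule with both landmarks computed from the model."""
        fp = find_background_fixed_point(params)
        return cls(
            mode=mode,
            eeg_threshold=sw_threshold(params),
            horizon=horizon,
            vicinity_radius=vicinity_radius,
            fixed_point=fp,
        )


def classify_outcome(traj: Trajectory, rule: ClassificationRule, t_ref: float) -> str:
    """Label a trajectory 'background' or 'seizure' at reference time t_ref.

    The trajectory must cover [t_ref, t_ref + rule.span]; anything
    shorter raises rather than classifying on partial evidence.
    """
    t_end = t_ref + rule.span
    eps = 1e-9
    if traj.times[0] > t_ref + eps or traj.times[-1] < t_end - eps:
        raise ValueError(
            f"trajectory [{traj.times[0]:.4g}, {traj.times[-1]:.4g}] does not "
            f"cover the classification window [{t_ref:.4g}, {t_end:.4g}]"
        )
    if rule.mode == "eeg_threshold":
        window = (traj.times >= t_ref - eps) & (traj.times <= t_end + eps)
        ok = np.all(traj.eeg[window] <= rule.eeg_threshold)
        return "background" if ok else "seizure"
    if rule.mode == "sw_termination":
        tail = (traj.times >= t_ref + rule.horizon - eps) & \
               (traj.times <= t_end + eps)
        ok = np.all(traj.eeg[tail] <= rule.eeg_threshold)
        return "background" if ok else "seizure"
    x_end = traj.state_at(t_ref + rule.horizon)
    dist = float(np.linalg.norm(x_end - rule.fixed_point))
    return "background" if dist <= rule.vicinity_radius else "seizure"


def _classify_from(
    params: ModelParameters,
    x0: np.ndarray,
    rule: ClassificationRule,
    plan: NoisePlan,
) -> str:
    thin = max(int(round(1.0 / (SCAN_FS * plan.dt))), 1)
    traj = integrate_stochastic(params, x0, rule.span, plan, thin=thin)
    return classify_outcome(traj, rule, 0.0)


def estimate_return_probability(
    params: ModelParameters,
    x0,
    rule: ClassificationRule,
    n_trials: int = 20,
    base_seed: int = 0,
    dt: float = DEFAULT_DT,
    seed_key: tuple[int, ...] = (),
) -> float:
    """Fraction of noise realizations from x0 that return to background.

    With alpha = 0 a single deterministic trial decides (returns exactly
    0.0 or 1.0 regardless of n_trials). Trial streams are derived from
    (base_seed, *seed_key, trial_index), so results do not depend on
    evaluation order; seed_key lets grid scans give every point its own
    family of streams.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    x0 = np.asarray(x0, dtype=float)
    if params.alpha == 0:
        label = _classify_from(params, x0, rule, NoisePlan(dt=dt, sd=0.0))
        return 1.0 if label == "background" else 0.0
    successes = 0
    for i in range(n_trials):
        plan = NoisePlan(dt=dt, sd=params.alpha,
                         seed_pre=trial_seed(base_seed, *seed_key, i))
        try:
            label = _classify_from(params, x0, rule, plan)
        except Exception as exc:
            raise RuntimeError(f"trial {i} from x0={x0} failed") from exc
        successes += label == "background"
    return successes / n_trials


@dataclass
class SliceSpec:
    """An axis-aligned slice through the 4-D state space.

    ``fixed_axes`` maps 1 or 2 variable names to fixed values; the
    remaining variables carry inclusive (min, max, n) grids.
    """

    fixed_axes: dict[str, float]
    free_axes: dict[str, tuple[float, float, int]]

    def __post_init__(self) -> None:
        names = set(self.fixed_axes) | set(self.free_axes)
        if names != set(STATE_NAMES) or set(self.fixed_axes) & set(self.free_axes):
            raise ValueError(
                "fixed_axes and free_axes must partition "
                f"{STATE_NAMES}, got fixed={list(self.fixed_axes)} "
                f"free={list(self.free_axes)}"
            )
        if not 1 <= len(self.fixed_axes) <= 2:
            raise ValueError("1 or 2 axes must be fixed")
        for name, (lo, hi, n) in self.free_axes.items():
            if n < 2:
                raise ValueError(f"free axis {name} needs n_points >= 2")

    def grids(self) -> dict[str, np.ndarray]:
        return {
            name: np.linspace(lo, hi, n)
            for name, (lo, hi, n) in self.free_axes.items()
        }

    def points(self):
        """Yield (index tuple, full 4-D state) over the grid, C-order."""
        grids = self.grids()
        names = list(grids)
        shape = [len(grids[n]) for n in names]
        base = np.empty(4)
        for name, val in self.fixed_axes.items():
            base[STATE_NAMES.index(name)] = val
        for idx in np.ndindex(*shape):
            x = base.copy()
            for k, name in enumerate(names):
                x[STATE_NAMES.index(name)] = grids[name][idx[k]]
            yield idx, x


@dataclass
class BasinGrid:
    """Scan result: per-grid-point return probability (or 0/1 label)."""

    slice_spec: SliceSpec
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        grids = self.slice_spec.grids()
        names = list(grids)
        mesh = np.meshgrid(*[grids[n] for n in names], indexing="ij")
        data = {n: m.ravel() for n, m in zip(names, mesh)}
        for name, val in self.slice_spec.fixed_axes.items():
            data[name] = np.full(self.values.size, val)
        data["value"] = self.values.ravel()
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def basin_points(self, threshold: float = 0.5) -> np.ndarray:
        """Point cloud (n, 4) of grid states with value > threshold."""
        df = self.to_frame()
        sel = df[df["value"] > threshold]
        return sel[list(STATE_NAMES)].to_numpy()

    def basin_fraction(self, threshold: float = 0.5) -> float:
        return float(np.mean(self.values > threshold))


def scan_basin(
    params: ModelParameters,
    slice_spec: SliceSpec,
    rule: ClassificationRule,
    n_trials: int = 20,
    base_seed: int = 0,
    dt: float = DEFAULT_DT,
) -> BasinGrid:
    """Return probability (or binary membership) at every slice grid point.

    Each point is evaluated independently with its own seed stream
    keyed by the point's linear index, so the result is independent of
    evaluation order or chunking.
    """
    grids = slice_spec.grids()
    shape = tuple(len(grids[n]) for n in grids)
    values = np.empty(shape)
    for idx, x in slice_spec.points():
        lin = int(np.ravel_multi_index(idx, shape))
        try:
            values[idx] = estimate_return_probability(
                params, x, rule, n_trials=(n_trials if params.alpha > 0 else 1),
                base_seed=base_seed, dt=dt, seed_key=(lin,),
            )
        except Exception as exc:
            raise RuntimeError(f"scan failed at grid index {idx}, state {x}") from exc
    return BasinGrid(
        slice_spec,
        values,
        metadata={
            "params": params.to_yaml(),
            "rule_mode": rule.mode,
            "n_trials": 1 if params.alpha == 0 else n_trials,
            "base_seed": base_seed,
            "dt": dt,
        },
    )


def slice_along_attractor(
    params: ModelParameters,
    cycle: Trajectory,
    slice_times,
    grid_template: dict[str, tuple[float, float, int]],
    rule: ClassificationRule,
    dt: float = DEFAULT_DT,
) -> list[BasinGrid]:
    """3-D basin slices with the fourth variable pinned to the attractor.

    ``grid_template`` fixes the grids of exactly three variables; for
    each slice time the remaining variable is held at its value on the
    supplied SW cycle, and the slice is scanned deterministically.
    """
    missing = set(STATE_NAMES) - set(grid_template)
    if len(missing) != 1:
        raise ValueError("grid_template must cover exactly three variables")
    fixed_name = missing.pop()
    col = STATE_NAMES.index(fixed_name)
    out = []
    for t in slice_times:
        if not cycle.times[0] <= t <= cycle.times[-1]:
            raise ValueError(f"slice time {t} outside cycle span")
        val = float(np.interp(t, cycle.times, cycle.states[:, col]))
        spec = SliceSpec(fixed_axes={fixed_name: val}, free_axes=dict(grid_template))
        grid = scan_basin(params, spec, rule, n_trials=1, dt=dt)
        grid.metadata["slice_time"] = t
        grid.metadata["fixed_value"] = val
        out.append(grid)
    return out


def classify_attractor_regime(
    params: ModelParameters,
    probe_window: float = 10.0,
    kick_magnitude: float = abs(SEIZURE_KICK),
    dt: float = DEFAULT_DT,
) -> str:
    """Four-way attractor census of the deterministic model.

    Tests (i) existence/stability of the background equilibrium and its
    persistence over a probe window, and (ii) whether a strong cortical
    pulse applied after 3 s of rest ignites a sustained large-amplitude
    oscillation. Both pulse signs are probed so the label does not
    depend on the sign convention. Probes run on the same fixed-step
    discretization as the stochastic experiments.
    """
    if params.alpha != 0:
        raise ValueError("regime classification requires alpha = 0 "
                         "(pass params.replace(alpha=0.0))")
    try:
        fp = find_background_fixed_point(params)
        fp_ok = True
    except (FixedPointError, UnstableFixedPointError):
        fp_ok = False
        fp = params.h  # fallback start for the oscillation probe

    plan = NoisePlan(dt=dt, sd=0.0)
    thin = max(int(round(1.0 / (SCAN_FS * dt))), 1)
    if fp_ok:
        probe = integrate_stochastic(params, fp, probe_window, plan, thin=thin)
        drift = np.max(np.abs(probe.states - fp))
        fp_ok = drift < 1e-3

    sustained = False
    for sign in (+1.0, -1.0):
        x0 = np.asarray(fp, dtype=float).copy()
        rest = integrate_stochastic(params, x0, 3.0, plan, thin=thin)
        x = rest.states[-1].copy()
        x[0] += sign * kick_magnitude
        x[1] += sign * kick_magnitude
        try:
            post = integrate_stochastic(params, x, probe_window, plan, thin=thin)
        except Exception:
            continue
        tail = post.eeg[int(len(post) * 0.8):]
        if tail.max() - tail.min() > 0.1:
            sustained = True
            break

    if fp_ok and sustained:
        return "bistable"
    if fp_ok:
        return "monostable_background"
    if sustained:
        return "monostable_swd"
    return "other"


def scan_parameter_1d(
    params: ModelParameters,
    name: str,
    value_range: tuple[float, float],
    n_points: int,
    **probe_kw,
):
    """Regime label along a 1-D parameter sweep, plus bistable intervals.

    Returns (values, regimes, intervals) where intervals are the
    contiguous (lo, hi) value ranges labelled bistable.
    """
    if not hasattr(params, name):
        raise ValueError(f"unknown parameter {name!r}")
    lo, hi = value_range
    if n_points < 1 or (n_points < 2 and lo != hi):
        raise ValueError("n_points must be >= 2 for a non-degenerate range")
    values = np.linspace(lo, hi, n_points) if lo != hi else np.array([lo])
    regimes = []
    for v in values:
        p = params.replace(**{name: float(v)})
        regimes.append(classify_attractor_regime(p, **probe_kw))
    intervals = []
    start = None
    for v, r in zip(values, regimes):
        if r == "bistable" and start is None:
            start = v
        elif r != "bistable" and start is not None:
            intervals.append((float(start), float(prev)))
            start = None
        prev = v
    if start is not None:
        intervals.append((float(start), float(values[-1])))
    return values, regimes, intervals
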
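"""Single-pulse stimulation trials and success-rate maps.

A stimulus is modelled as an instantaneous reset of selected state
variables: at the stimulation time the state jumps by ``amplitude *
direction``. The default direction (1, 1, 0, 0) delivers equal input
to both cortical populations, emulating an unspecific cortical pulse
(e.g. TMS) whose direction in state space cannot be steered.

A timing x amplitude scan over a seizure segment yields a success-rate
map: in the deterministic setting each cell is a binary outcome (the
pulse either lands in the background basin or it does not); in the
noise-driven setting each cell is the fraction of post-stimulus noise
realizations (20 by default) for which the seizure terminates within
the 3-s horizon, with the pre-stimulus segment held fixed across
realizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attractor import find_spike_peaks
from .basin import SCAN_FS, ClassificationRule, classify_outcome
from .integrate import (
    DEFAULT_DT,
    NoisePlan,
    integrate_deterministic,
    integrate_stochastic,
    trial_seed,
)
from .model import ModelParameters, Trajectory

__all__ = [
    "StimulusSpec",
    "TrialResult",
    "SuccessRateMap",
    "apply_pulse",
    "run_trial",
    "scan_stimulation",
    "count_success_phases",
    "summarize_map",
]

CORTICAL_DIRECTION = np.array([1.0, 1.0, 0.0, 0.0])


@dataclass
class StimulusSpec:
    """A single pulse: when, how strong, and along which direction."""

    t_s: float
    amplitude: float
    direction: np.ndarray = field(default_factory=lambda: CORTICAL_DIRECTION.copy())

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        if self.direction.shape != (4,) or not np.any(self.direction):
            raise ValueError("direction must be a 4-vector with a nonzero component")


def apply_pulse(state, stim: StimulusSpec) -> np.ndarray:
    """Instantaneous state reset: state + amplitude * direction."""
    return np.asarray(state, dtype=float) + stim.amplitude * stim.direction


@dataclass
class TrialResult:
    outcome: str
    trajectory: Trajectory
    post_sw_duration: float | None = None


def _post_sw_duration(traj: Trajectory, t_s: float, rule: ClassificationRule) -> float | None:
    """Time from the pulse to the last super-threshold EEG sample."""
    if rule.eeg_threshold is None:
        return None
    post = (traj.times >= t_s) & (traj.eeg > rule.eeg_threshold)
    if not post.any():
        return 0.0
    return float(traj.times[np.flatnonzero(post)[-1]] - t_s)


def run_trial(
    params: ModelParameters,
    x0,
    pre_span: float,
    stim: StimulusSpec,
    rule: ClassificationRule,
    plan: NoisePlan | None = None,
    post_span: float | None = None,
) -> TrialResult:
    """Simulate, pulse at t_s, continue, classify at t_ref = t_s.

    Deterministic trials (plan None) integrate with the adaptive solver
    and apply the pulse to the interpolated state at t_s; stochastic
    trials use the fixed-step scheme (the pulse lands on the step state)
    and must set ``plan.switch_time == t_s`` so the pre-stimulus noise
    is shared across trials while the post-stimulus noise varies.
    """
    if not 0.0 <= stim.t_s <= pre_span:
        raise ValueError(f"t_s={stim.t_s} outside the simulated span [0, {pre_span}]")
    if post_span is None:
        post_span = rule.span + 0.6
    if post_span < rule.span:
        raise ValueError("post_span must cover the classification horizon")

    if plan is None:
        if stim.t_s > 0:
            pre = integrate_deterministic(params, x0, stim.t_s, sample_rate=SCAN_FS)
            x_at = pre.state_at(stim.t_s, interpolate=True)
        else:
            pre = None
            x_at = np.asarray(x0, dtype=float)
        x_pulsed = apply_pulse(x_at, stim)
        post = integrate_deterministic(params, x_pulsed, post_span, sample_rate=SCAN_FS)
    else:
        if plan.switch_time is None or abs(plan.switch_time - stim.t_s) > plan.dt / 2:
            raise ValueError("stochastic trials require plan.switch_time == stim.t_s")
        thin = max(int(round(1.0 / (SCAN_FS * plan.dt))), 1)
        if stim.t_s > 0:
            pre_plan = NoisePlan(dt=plan.dt, seed_pre=plan.seed_pre, sd=plan.sd)
            pre = integrate_stochastic(params, x0, stim.t_s, pre_plan, thin=thin)
            x_at = pre.states[-1]
        else:
            pre = None
            x_at = np.asarray(x0, dtype=float)
        x_pulsed = apply_pulse(x_at, stim)
        post_plan = NoisePlan(dt=plan.dt, seed_pre=plan.seed_post, sd=plan.sd)
        post = integrate_stochastic(params, x_pulsed, post_span, post_plan, thin=thin)

    if pre is not None:
        times = np.concatenate([pre.times[:-1], post.times + stim.t_s])
        states = np.vstack([pre.states[:-1], post.states])
        traj = Trajectory(times, states)
    else:
        traj = Trajectory(post.times + stim.t_s, post.states)
    outcome = classify_outcome(traj, rule, t_ref=stim.t_s)
    return TrialResult(outcome, traj, _post_sw_duration(traj, stim.t_s, rule))


@dataclass
class SuccessRateMap:
    """Stimulation outcomes over (timing x amplitude x noise seed)."""

    time_grid: np.ndarray
    amplitude_grid: np.ndarray
    outcomes: np.ndarray  # bool, shape (n_times, n_amplitudes, n_seeds)
    cycle_boundaries: np.ndarray
    direction: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def rates(self) -> np.ndarray:
        """Per-cell success rate, averaged over the seed axis."""
        return self.outcomes.mean(axis=2)

    @property
    def n_seeds(self) -> int:
        return self.outcomes.shape[2]

    def to_frame(self):
        import pandas as pd

        nt, na, ns = self.outcomes.shape
        t, a, s = np.meshgrid(
            self.time_grid, self.amplitude_grid, np.arange(ns), indexing="ij"
        )
        return pd.DataFrame(
            {
                "t": t.ravel(),
                "amplitude": a.ravel(),
                "seed": s.ravel(),
                "outcome": self.outcomes.ravel().astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def scan_stimulation(
    params: ModelParameters,
    seizure_segment: Trajectory,
    time_grid,
    amplitude_grid,
    direction=CORTICAL_DIRECTION,
    rule: ClassificationRule | None = None,
    n_seeds: int = 20,
    base_seed: int = 0,
    dt: float = DEFAULT_DT,
) -> SuccessRateMap:
    """Success-rate map over a seizure segment.

    The pre-stimulus history is the supplied seizure segment itself
    (one shared realization): for each (time, amplitude, seed) cell the
    pulse is applied to the segment's state at that time and the model
    is continued for the classification horizon with an independent
    post-stimulus noise stream keyed by (base_seed, cell indices). With
    alpha = 0 and n_seeds = 1 the scan is fully deterministic and the
    pulse target is the interpolated segment state.
    """
    if rule is None:
        rule = ClassificationRule.for_model(params, mode="sw_termination")
    time_grid = np.asarray(time_grid, dtype=float)
    amplitude_grid = np.asarray(amplitude_grid, dtype=float)
    if time_grid.min() < seizure_segment.times[0] - 1e-9 or \
       time_grid.max() > seizure_segment.times[-1] + 1e-9:
        raise ValueError("time_grid extends beyond the seizure segment")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    stochastic = params.alpha > 0
    thin = max(int(round(1.0 / (SCAN_FS * dt))), 1)
    outcomes = np.zeros((len(time_grid), len(amplitude_grid), n_seeds), dtype=bool)
    for it, t in enumerate(time_grid):
        x_t = seizure_segment.state_at(t, interpolate=not stochastic)
        for ia, amp in enumerate(amplitude_grid):
            stim = StimulusSpec(t_s=t, amplitude=float(amp), direction=direction)
            x_pulsed = apply_pulse(x_t, stim)
            for isd in range(n_seeds):
                plan = NoisePlan(
                    dt=dt,
                    sd=params.alpha if stochastic else 0.0,
                    seed_pre=trial_seed(base_seed, it, ia, isd),
                )
                try:
                    post = integrate_stochastic(
                        params, x_pulsed, rule.span, plan, thin=thin
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"trial failed at cell (t={t}, amplitude={amp}, seed={isd})"
                    ) from exc
                outcomes[it, ia, isd] = (
                    classify_outcome(post, rule, 0.0) == "background"
                )

    boundaries = _cycle_boundaries(seizure_segment, rule)
    return SuccessRateMap(
        time_grid=time_grid,
        amplitude_grid=amplitude_grid,
        outcomes=outcomes,
        cycle_boundaries=boundaries,
        direction=np.asarray(direction, dtype=float),
        metadata={
            "params": params.to_yaml(),
            "rule_mode": rule.mode,
            "n_seeds": n_seeds,
            "base_seed": base_seed,
            "dt": dt,
        },
    )


def _cycle_boundaries(segment: Trajectory, rule: ClassificationRule) -> np.ndarray:
    """SW cycle delimiters: successive spike peaks of the segment's EEG."""
    if rule.eeg_threshold is None:
        return np.array([])
    fs = segment.fs
    peaks = find_spike_peaks(segment.eeg, fs, rule.eeg_threshold)
    return segment.times[peaks]


def count_success_phases(row) -> int:
    """Number of maximal contiguous success runs over one cycle.

    The row is aligned to a single cycle, so a run touching both ends
    wraps around the cycle boundary and counts once.
    """
    row = np.asarray(row, dtype=bool)
    if row.size == 0:
        return 0
    edges = int(np.sum(np.diff(row.astype(int)) == 1)) + int(row[0])
    if row[0] and row[-1] and not row.all():
        edges -= 1  # wrap-around: first and last runs are the same phase
    return edges


def summarize_map(srm: SuccessRateMap, phase_rate_threshold: float = 0.5) -> dict:
    """Headline statistics of a success-rate map.

    mean_rate              mean over all cells;
    per_amplitude_mean     mean over the time axis for each amplitude;
    best_amplitude         amplitude with the largest row mean;
    max_amplitude_mean     that largest row mean;
    max_cell_rate          best single cell;
    min_effective_amplitude  smallest |amplitude| with any success;
    phases_per_cycle       per amplitude and per cycle, the number of
                           contiguous successful phases (cells count as
                           successful when their rate exceeds
                           ``phase_rate_threshold``; for deterministic
                           maps the rates are already 0/1).
    """
    rates = srm.rates
    per_amp = rates.mean(axis=0)
    best = int(np.argmax(per_amp))
    succ_any = rates.max(axis=0) > 0
    min_eff = (
        float(np.min(np.abs(srm.amplitude_grid[succ_any]))) if succ_any.any() else None
    )
    phases = {}
    bounds = srm.cycle_boundaries
    if len(bounds) >= 2:
        for ia, amp in enumerate(srm.amplitude_grid):
            counts = []
            for b0, b1 in zip(bounds[:-1], bounds[1:]):
                sel = (srm.time_grid >= b0) & (srm.time_grid < b1)
                counts.append(
                    count_success_phases(rates[sel, ia] > phase_rate_threshold)
                )
            phases[float(amp)] = counts
    return {
        "mean_rate": float(rates.mean()),
        "per_amplitude_mean": per_amp.tolist(),
        "best_amplitude": float(srm.amplitude_grid[best]),
        "max_amplitude_mean": float(per_amp[best]),
        "max_cell_rate": float(rates.max()),
        "min_effective_amplitude": min_eff,
        "phases_per_cycle": phases,
    }
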
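"""High-level experiment recipes.

These functions bundle the standard study conditions — the noise
preset's spontaneous-seizure runs, the spike-wave complex duration
measurement, and the headline stimulation success-rate map — so the
command-line interface, the test suite and reproduction scripts all
run the identical procedure.
"""

from __future__ import annotations

import numpy as np

from .attractor import find_spike_peaks
from .basin import ClassificationRule
from .embed import SeizureEpisode, detect_seizures
from .integrate import DEFAULT_DT, NoisePlan, integrate_stochastic
from .model import ModelParameters, Trajectory, eeg_observable, find_background_fixed_point
from .stimulate import SuccessRateMap, scan_stimulation

__all__ = [
    "simulate_noisy",
    "seizure_episodes",
    "sw_complex_duration",
    "noisy_seizure_segment",
    "headline_map",
    "HEADLINE_N_TIMES",
    "HEADLINE_N_AMPLITUDES",
    "HEADLINE_AMPLITUDE_RANGE",
    "HEADLINE_WINDOW",
    "HEADLINE_ONSET_OFFSET",
    "HEADLINE_N_SEEDS",
]

# Headline stimulation-map conditions: stimulation times cover 3 s of an
# established noise-driven seizure (starting 0.3 s after detected onset,
# so the SW rhythm is fully developed and typical episodes outlast the
# window), and each cell averages 20 post-stimulus noise realizations.
# The amplitude range is shared with the deterministic cycle scan: it
# covers the negative (cortically suppressive) pulses from just above
# zero down to beyond the six-phase regime, bracketing the reference
# pulse of -0.0825.
HEADLINE_N_TIMES = 60
HEADLINE_N_AMPLITUDES = 15
HEADLINE_AMPLITUDE_RANGE = (-0.30, -0.01)
HEADLINE_WINDOW = 3.0
HEADLINE_ONSET_OFFSET = 0.3
HEADLINE_N_SEEDS = 20

# Deterministic one-cycle scan (timing x amplitude over a single SW
# cycle of the deterministic preset).
CYCLE_SCAN_N_TIMES = 200
CYCLE_SCAN_N_AMPLITUDES = 59
CYCLE_SCAN_AMPLITUDE_RANGE = HEADLINE_AMPLITUDE_RANGE


def simulate_noisy(
    params: ModelParameters,
    t_end: float,
    base_seed: int,
    dt: float = DEFAULT_DT,
    fs_out: float = 1000.0,
) -> Trajectory:
    """Noise-driven run from the background fixed point."""
    fp = find_background_fixed_point(params)
    plan = NoisePlan(dt=dt, sd=params.alpha, seed_pre=base_seed)
    thin = max(int(round(1.0 / (fs_out * dt))), 1)
    return integrate_stochastic(params, fp, t_end, plan, thin=thin)


def seizure_episodes(
    params: ModelParameters,
    traj: Trajectory,
    rule: ClassificationRule | None = None,
) -> list[SeizureEpisode]:
    """Detected SW episodes of a model trajectory.

    Detection baseline is the background fixed-point EEG; the detection
    threshold is the SW threshold expressed as a deviation from it.
    """
    if rule is None:
        rule = ClassificationRule.for_model(params)
    base = eeg_observable(rule.fixed_point)
    return detect_seizures(
        traj.eeg, traj.fs,
        threshold=rule.eeg_threshold - base,
        baseline=base,
    )


def sw_complex_duration(
    params: ModelParameters,
    base_seed: int,
    t_end: float = 600.0,
    dt: float = DEFAULT_DT,
    return_count: bool = False,
):
    """Median spike-to-spike duration (s) of one SW complex.

    Measured inside spontaneous noise-driven seizures: successive EEG
    spike peaks are detected within each episode and the median
    inter-peak interval over all episodes is returned.
    """
    rule = ClassificationRule.for_model(params)
    intervals: list[float] = []
    for attempt in range(6):  # pool several spans for a stable median
        seed = base_seed + 1_000_003 * attempt
        traj = simulate_noisy(params, t_end, seed, dt=dt)
        for ep in seizure_episodes(params, traj, rule):
            seg = traj.window(ep.onset, ep.offset)
            peaks = find_spike_peaks(seg.eeg, seg.fs, rule.eeg_threshold)
            if len(peaks) >= 2:
                d = np.diff(seg.times[peaks])
                intervals.extend(d[d < 0.6])  # within-seizure intervals only
        if len(intervals) >= 30:
            break
    if not intervals:
        raise RuntimeError(
            f"no seizure with >= 2 spikes found near seed {base_seed}"
        )
    median = float(np.median(intervals))
    return (median, len(intervals)) if return_count else median


def noisy_seizure_segment(
    params: ModelParameters,
    base_seed: int,
    dt: float = DEFAULT_DT,
    window: float = HEADLINE_WINDOW,
    offset: float = HEADLINE_ONSET_OFFSET,
    search_span: float = 600.0,
    rule: ClassificationRule | None = None,
) -> Trajectory:
    """A window of an established spontaneous seizure, time rebased to 0.

    Simulates the noisy model until an episode at least ``offset +
    window`` long is found and cuts out the scan window starting
    ``offset`` seconds after detected onset. Consecutive search seeds
    are derived from base_seed if a span contains no such episode.
    """
    if rule is None:
        rule = ClassificationRule.for_model(params)
    need = offset + window
    for attempt in range(5):
        seed = base_seed + 1_000_003 * attempt
        traj = simulate_noisy(params, search_span, seed, dt=dt)
        for ep in seizure_episodes(params, traj, rule):
            if ep.duration >= need:
                seg = traj.window(ep.onset + offset, ep.onset + offset + window)
                return Trajectory(seg.times - seg.times[0], seg.states)
    raise RuntimeError(
        f"no seizure of duration >= {need} s found in {5 * search_span} s"
    )


def deterministic_cycle_map(
    params: ModelParameters | None = None,
    n_times: int = CYCLE_SCAN_N_TIMES,
    n_amplitudes: int = CYCLE_SCAN_N_AMPLITUDES,
    dt: float = DEFAULT_DT,
) -> SuccessRateMap:
    """Noise-free timing x amplitude scan over one SW cycle."""
    from .attractor import sw_cycle

    if params is None:
        params = ModelParameters.deterministic()
    rule = ClassificationRule.for_model(params, mode="sw_termination")
    cycle = sw_cycle(params)
    times = np.linspace(cycle.times[0], cycle.times[-1] - 1e-3, n_times)
    amps = np.linspace(*CYCLE_SCAN_AMPLITUDE_RANGE, n_amplitudes)
    return scan_stimulation(
        params, cycle, times, amps, rule=rule, n_seeds=1, dt=dt,
    )


def headline_map(
    params: ModelParameters,
    base_seed: int,
    dt: float = DEFAULT_DT,
    n_times: int = HEADLINE_N_TIMES,
    n_amplitudes: int = HEADLINE_N_AMPLITUDES,
    n_seeds: int = HEADLINE_N_SEEDS,
) -> SuccessRateMap:
    """The noise-driven stimulation success-rate map at study conditions."""
    rule = ClassificationRule.for_model(params, mode="sw_termination")
    segment = noisy_seizure_segment(params, base_seed, dt=dt)
    times = np.linspace(segment.times[0], segment.times[-1] - 1e-3, n_times)
    amps = np.linspace(*HEADLINE_AMPLITUDE_RANGE, n_amplitudes)
    return scan_stimulation(
        params, segment, times, amps, rule=rule,
        n_seeds=n_seeds, base_seed=base_seed, dt=dt,
    )
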
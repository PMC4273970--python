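"""Locating the spike-wave limit cycle and its landmarks.

The bistable model has two coexisting invariant sets: the stable
background equilibrium and the spike-wave (SW) limit cycle. A strong
cortical perturbation from the equilibrium (the same PY+IN direction
used for stimulation) crosses the separatrix and, after a transient,
the flow settles onto the cycle. These helpers provide on-attractor
states, spike-peak detection, cycle extraction and the period/threshold
landmarks that the basin and stimulation modules build on.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

from .integrate import DEFAULT_DT, NoisePlan, integrate_deterministic, integrate_stochastic
from .model import ModelParameters, Trajectory, eeg_observable, find_background_fixed_point

__all__ = [
    "SEIZURE_KICK",
    "attractor_state",
    "sw_cycle",
    "find_spike_peaks",
    "sw_period",
    "sw_threshold",
]

#: Standard strong cortical perturbation (applied to PY and IN equally)
#: used to knock the model from the background equilibrium across the
#: separatrix onto the SW attractor. The sign convention follows the
#: stimulation experiments (negative = transient cortical suppression);
#: magnitude 0.6 lies well beyond the basin boundary.
SEIZURE_KICK = -0.6


def attractor_state(
    params: ModelParameters,
    transient: float = 20.0,
    kick: float = SEIZURE_KICK,
    method: str = "euler",
) -> np.ndarray:
    """A state on the SW attractor, after discarding a transient.

    The default integrator is the fixed-step scheme at the stochastic
    step size: the noise preset's SW cycle is maintained by exactly
    that discretization (its fold under the exact flow lies marginally
    past h_tc = -2.05), so attractor landmarks must be computed on the
    discretization the experiments run on. ``method='rk45'`` uses the
    adaptive solver instead; for the deterministic preset the two
    agree.
    """
    fp = find_background_fixed_point(params)
    x0 = fp.copy()
    x0[0] += kick
    x0[1] += kick
    if method == "euler":
        traj = integrate_stochastic(
            params, x0, transient, NoisePlan(dt=DEFAULT_DT, sd=0.0), thin=10
        )
    else:
        traj = integrate_deterministic(params, x0, transient, sample_rate=500.0)
    x = traj.states[-1]
    tail = traj.eeg[int(len(traj) * 0.8):]
    if tail.max() - tail.min() < 0.1:
        raise RuntimeError(
            "perturbed trajectory relaxed back to background; no SW "
            "attractor reached (is the model bistable at these parameters?)"
        )
    return x


def find_spike_peaks(
    eeg: np.ndarray,
    fs: float,
    height: float,
    min_separation: float = 0.2,
) -> np.ndarray:
    """Indices of EEG spike maxima above `height`.

    The separation floor (default 0.2 s, below the ~0.3 s SW cycle)
    keeps only the dominant spike when the slow-wave hump of the same
    complex also pokes above the threshold.
    """
    peaks, _ = find_peaks(eeg, height=height, distance=max(int(min_separation * fs), 1))
    return peaks


def sw_threshold(params: ModelParameters, attractor_x=None) -> float:
    """EEG threshold separating background from SW oscillation.

    Midpoint between the background fixed-point EEG and the maximum EEG
    of the zero-noise SW cycle (fixed-step integration, see
    :func:`attractor_state`).
    """
    fp = find_background_fixed_point(params)
    x = attractor_state(params) if attractor_x is None else attractor_x
    traj = integrate_stochastic(
        params, x, 2.0, NoisePlan(dt=DEFAULT_DT, sd=0.0), thin=2
    )
    return 0.5 * (eeg_observable(fp) + float(traj.eeg.max()))


def sw_cycle(params: ModelParameters, sample_rate: float = 1000.0) -> Trajectory:
    """One full SW cycle, delimited spike peak to spike peak.

    The returned trajectory starts at a spike maximum of the EEG and
    ends one period later (inclusive), with time rebased to 0.
    """
    x = attractor_state(params)
    traj = integrate_deterministic(params, x, 3.0, sample_rate=sample_rate)
    thr = sw_threshold(params, attractor_x=x)
    peaks = find_spike_peaks(traj.eeg, sample_rate, thr)
    if len(peaks) < 2:
        raise RuntimeError("fewer than two spike peaks found on attractor run")
    seg = Trajectory(
        traj.times[peaks[0]: peaks[1] + 1] - traj.times[peaks[0]],
        traj.states[peaks[0]: peaks[1] + 1],
    )
    return seg


def sw_period(params: ModelParameters, span: float = 5.0) -> float:
    """Median spike-peak-to-spike-peak period (s) of the deterministic cycle."""
    x = attractor_state(params)
    traj = integrate_deterministic(params, x, span, sample_rate=1000.0)
    thr = sw_threshold(params, attractor_x=x)
    peaks = find_spike_peaks(traj.eeg, 1000.0, thr)
    if len(peaks) < 3:
        raise RuntimeError("not enough spike peaks to estimate a period")
    return float(np.median(np.diff(traj.times[peaks])))
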
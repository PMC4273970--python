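"""Delay embedding, low-pass filtering, seizure detection, and
state-space success binning.

Attractor geometry can be reconstructed from a single scalar series
(the model EEG, or a clinical recording) by time-delay embedding. The
model is a fast-slow system, so a low-pass filter (6 Hz cutoff by
default, zero-phase) is applied first to recover the slow variables;
the delayed copies (~0.06 s apart) then span a space comparable to the
model's own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "EmbeddingSpec",
    "SeizureEpisode",
    "lowpass_filter",
    "delay_embed",
    "detect_seizures",
    "bin_state_space_success",
]


@dataclass
class EmbeddingSpec:
    """Low-pass + delay-embedding parameters."""

    cutoff: float = 6.0       # Hz
    delay: float = 0.06       # s
    dimension: int = 3
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.delay <= 0:
            raise ValueError("delay must be > 0")
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")


def lowpass_filter(series, fs: float, spec: EmbeddingSpec | None = None) -> np.ndarray:
    """Zero-phase Butterworth low-pass; same length as the input."""
    spec = spec or EmbeddingSpec()
    if fs <= 2 * spec.cutoff:
        raise ValueError(
            f"cutoff {spec.cutoff} Hz at or above Nyquist ({fs / 2} Hz)"
        )
    b, a = butter(spec.filter_order, spec.cutoff, btype="low", fs=fs)
    return filtfilt(b, a, np.asarray(series, dtype=float))


def delay_embed(series, fs: float, spec: EmbeddingSpec | None = None) -> np.ndarray:
    """Takens delay embedding: point k = (x[k], x[k+L], ..., x[k+(d-1)L]).

    L = round(delay * fs). Output shape (n - (d-1)*L, d).
    """
    spec = spec or EmbeddingSpec()
    x = np.asarray(series, dtype=float)
    L = int(round(spec.delay * fs))
    d = spec.dimension
    n_out = len(x) - (d - 1) * L
    if L < 1 or n_out < 1:
        raise ValueError(
            f"series of length {len(x)} too short for {d}-dimensional "
            f"embedding with lag {L} samples"
        )
    return np.column_stack([x[k * L: k * L + n_out] for k in range(d)])


@dataclass
class SeizureEpisode:
    onset: float
    offset: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")


def detect_seizures(
    eeg,
    fs: float,
    threshold: float,
    baseline: float | None = None,
    min_duration: float = 1.0,
    merge_gap: float = 0.5,
) -> list[SeizureEpisode]:
    """Threshold-crossing episode detector for large-amplitude SW runs.

    Samples with |eeg - baseline| > threshold are marked; marked runs
    separated by gaps shorter than merge_gap are merged (the EEG dips
    through baseline once per SW cycle, so within-seizure gaps of a
    fraction of the ~0.3 s cycle must not split an episode); episodes
    shorter than min_duration are dropped. Baseline defaults to the
    series median.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    eeg = np.asarray(eeg, dtype=float)
    if baseline is None:
        baseline = float(np.median(eeg))
    above = np.abs(eeg - baseline) > threshold
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    episodes = []
    start = last = idx[0]
    for i in idx[1:]:
        if (i - last) / fs >= merge_gap:
            episodes.append((start, last))
            start = i
        last = i
    episodes.append((start, last))
    out = [
        SeizureEpisode(onset=s / fs, offset=(e + 1) / fs)
        for s, e in episodes
        if (e + 1 - s) / fs >= min_duration
    ]
    return out


def bin_state_space_success(points, outcomes, bin_width: float):
    """Per-bin success table over a uniformly binned embedding space.

    Bins are axis-aligned cubes of side ``bin_width`` anchored at the
    origin. Returns a DataFrame with one row per *visited* bin: the bin
    index tuple, attempt count, success count and success rate. Bins
    with no attempts are simply absent (never reported as rate 0).
    """
    import pandas as pd

    points = np.asarray(points, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    if len(points) != len(outcomes):
        raise ValueError("points and outcomes must have equal length")
    if len(points) == 0:
        return pd.DataFrame(columns=["bin", "attempts", "successes", "rate"])
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    keys = np.floor(points / bin_width).astype(int)
    records = {}
    for key, ok in zip(map(tuple, keys), outcomes):
        att, succ = records.get(key, (0, 0))
        records[key] = (att + 1, succ + int(ok))
    rows = [
        {"bin": k, "attempts": a, "successes": s, "rate": s / a}
        for k, (a, s) in sorted(records.items())
    ]
    return pd.DataFrame(rows)
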
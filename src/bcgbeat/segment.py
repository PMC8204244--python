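"""Motion-artifact segmentation by moving windowed variance.

When the seated person moves, the load-cell voltage swings far more than
the cardiac micro-forces do, so windows whose variance exceeds a threshold
tied to the recording's mean variance are treated as motion artifact and
discarded.  The rule: compute a 1 s moving windowed variance Var_mov,
discard every window with variance above ``factor * mean(Var_mov)``
(factor defaults to 1/2), and keep only surviving runs at least 5 s long —
long enough to hold several beats even at 40 bpm.

Two window layouts are provided: a true sliding variance (hop = 1 sample,
the default) and a non-overlapping "tiled" layout with one window per
second, which is the natural resolution for window-level bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import Recording

__all__ = [
    "VarianceSeries",
    "SegmentSet",
    "SegmentStats",
    "moving_variance",
    "find_clean_segments",
    "summarize_segments",
]


@dataclass(frozen=True)
class VarianceSeries:
    """Per-window sample variances of a recording."""

    values: np.ndarray       # variance per window, >= 0
    window_samples: int
    hop: int                 # samples between window starts
    fs: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("variance series must be a non-empty 1-D array")
        object.__setattr__(self, "values", v)

    def window_start(self, i: int) -> int:
        return i * self.hop


@dataclass(frozen=True)
class SegmentSet:
    """Disjoint clean (artifact-free) intervals, half-open in samples."""

    intervals: tuple[tuple[int, int], ...]
    n_samples: int
    fs: float
    min_duration_s: float

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.intervals:
            if not 0 <= start < end <= self.n_samples:
                raise ValueError(f"interval [{start}, {end}) out of range")
            if start < prev_end:
                raise ValueError("intervals overlap or are unsorted")
            prev_end = end

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([(e - s) / self.fs for s, e in self.intervals])

    @property
    def total_clean_s(self) -> float:
        return float(self.durations_s.sum()) if self.intervals else 0.0

    def contains_sample(self, i: int) -> bool:
        return any(s <= i < e for s, e in self.intervals)


@dataclass(frozen=True)
class SegmentStats:
    """Cohort-style summary of one recording's clean segments."""

    shortest_s: float
    longest_s: float
    count: int
    total_clean_s: float
    percent_clean: float


def moving_variance(recording: Recording, window_s: float = 1.0,
                    mode: str = "sliding") -> VarianceSeries:
    """Moving windowed variance of a recording.

    ``mode='sliding'`` evaluates every window start (hop = 1 sample) via
    cumulative sums; ``mode='tiled'`` evaluates non-overlapping windows
    (hop = window length), one value per second at the default window.
    """
    w = int(round(window_s * recording.fs))
    if w < 2:
        raise ValueError("variance window must span at least 2 samples")
    if recording.n < w:
        raise ValueError(
            f"recording ({recording.duration:.2f} s) shorter than one "
            f"{window_s} s window"
        )
    x = recording.samples
    if mode == "sliding":
        c1 = np.concatenate(([0.0], np.cumsum(x)))
        c2 = np.concatenate(([0.0], np.cumsum(x * x)))
        s1 = c1[w:] - c1[:-w]
        s2 = c2[w:] - c2[:-w]
        var = np.maximum(s2 / w - (s1 / w) ** 2, 0.0)
        hop = 1
    elif mode == "tiled":
        k = recording.n // w
        blocks = x[: k * w].reshape(k, w)
        var = blocks.var(axis=1)
        hop = w
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return VarianceSeries(var, window_samples=w, hop=hop, fs=recording.fs)


#: Relative spread below which a variance series counts as constant.
_CONSTANT_RTOL = 1e-9


def find_clean_segments(
    variance: VarianceSeries,
    threshold_factor: float = 0.5,
    min_duration_s: float = 5.0,
    n_samples: int | None = None,
) -> SegmentSet:
    """Apply the variance threshold rule and keep long clean runs.

    Threshold = ``threshold_factor * mean(Var_mov)``; windows above it are
    discarded as motion artifact.  A constant variance series (an all-clean
    recording: every window sits at the mean, hence trivially above half of
    it) is kept whole — the rule targets *large* variance excursions, and a
    spread-free series has none.  Runs of surviving windows shorter than
    ``min_duration_s`` are dropped; survivors are mapped back to sample
    coordinates (union of their windows).
    """
    if threshold_factor <= 0:
        raise ValueError("threshold factor must be positive")
    if min_duration_s <= 0:
        raise ValueError("minimum segment duration must be positive")
    v = variance.values
    w, hop = variance.window_samples, variance.hop
    if n_samples is None:
        n_samples = (v.size - 1) * hop + w

    mean_v = float(v.mean())
    spread = float(v.max() - v.min())
    if spread <= _CONSTANT_RTOL * max(abs(mean_v), 1e-300):
        keep = np.ones(v.size, dtype=bool)
    else:
        keep = v <= threshold_factor * mean_v

    intervals: list[tuple[int, int]] = []
    i = 0
    while i < v.size:
        if not keep[i]:
            i += 1
            continue
        j = i
        while j + 1 < v.size and keep[j + 1]:
            j += 1
        start, end = i * hop, min(j * hop + w, n_samples)
        if (end - start) / variance.fs >= min_duration_s:
            intervals.append((start, end))
        i = j + 1
    return SegmentSet(tuple(intervals), n_samples, variance.fs, min_duration_s)


def summarize_segments(segments: SegmentSet, duration_s: float | None = None) -> SegmentStats:
    """Summary statistics for a segment set (empty sets allowed)."""
    if duration_s is None:
        duration_s = segments.n_samples / segments.fs
    if len(segments) == 0:
        return SegmentStats(0.0, 0.0, 0, 0.0, 0.0)
    d = segments.durations_s
    total = float(d.sum())
    return SegmentStats(
        shortest_s=float(d.min()),
        longest_s=float(d.max()),
        count=len(segments),
        total_clean_s=total,
        percent_clean=100.0 * total / duration_s,
    )
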
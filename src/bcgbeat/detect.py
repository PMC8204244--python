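"""J-peak detection and beat-to-beat heart-rate estimation.

The detector works on the CWT row at the analysis scale (default: the
scale whose pseudo-frequency is ~6.8 Hz — scale 30 at fs = 250 Hz).  That
row shows one magnitude bump per heartbeat; its peaks mark heartbeat
windows 400 ms wide, the typical duration of a seated-BCG beat complex.
Within each window the J-peak candidate is the largest (signed) sample —
the J-wave is the dominant *positive* deflection.  Candidates must clear
an amplitude threshold (the mean absolute signal level over all heartbeat
windows) and respect a 500 ms refractory spacing, which caps the
detectable rate at 120 bpm; intervals implying rates outside [40, 120] bpm
are flagged invalid and excluded from the mean heart rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .recording import BeatAnnotation

__all__ = [
    "DetectionConfig",
    "HeartRateSummary",
    "locate_heartbeat_windows",
    "detect_jpeaks",
    "estimate_heart_rate",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Detector tuning; defaults follow the seated-BCG analysis recipe."""

    window_s: float = 0.400            # heartbeat window length
    min_spacing_s: float = 0.500       # J-to-J refractory period
    analysis_freq_hz: float = 6.770833333333333  # pseudo-frequency of scale 30 @ 250 Hz
    cwt_peak_separation_s: float = 0.400
    threshold_rule: str = "abs_mean"   # or "window_max_mean"
    hr_bounds_bpm: tuple[float, float] = (40.0, 120.0)

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.min_spacing_s <= 0:
            raise ValueError("window length and spacing must be positive")
        if self.threshold_rule not in ("abs_mean", "window_max_mean"):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")
        lo, hi = self.hr_bounds_bpm
        if not 0 < lo < hi:
            raise ValueError("heart-rate bounds must satisfy 0 < low < high")


DEFAULT_DETECTION = DetectionConfig()


@dataclass(frozen=True)
class HeartRateSummary:
    """Instantaneous rates from consecutive J-to-J intervals.

    ``mean_bpm`` averages only the valid intervals (those inside the
    physiologic bounds); it is None — never 0 — when no interval is usable.
    """

    instantaneous_bpm: np.ndarray
    valid: np.ndarray
    mean_bpm: float | None
    beat_count: int

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def locate_heartbeat_windows(
    row: np.ndarray,
    fs: float,
    config: DetectionConfig = DEFAULT_DETECTION,
) -> list[tuple[int, int]]:
    """Heartbeat windows from the CWT magnitude row at the analysis scale.

    Local maxima of |row| that clear the row's mean magnitude and are at
    least ``cwt_peak_separation_s`` apart become window centres; each
    window extends half a window length either side, clipped to the row.
    A flat row has no local maxima and yields no windows.
    """
    row = np.asarray(row, dtype=float)
    w = int(round(config.window_s * fs))
    if row.ndim != 1 or row.size == 0:
        raise ValueError("CWT row must be a non-empty 1-D array")
    if row.size < w:
        raise ValueError("CWT row shorter than one heartbeat window")
    mag = np.abs(row)
    centers, _ = find_peaks(
        mag,
        height=mag.mean(),
        distance=max(int(round(config.cwt_peak_separation_s * fs)), 1),
    )
    half = w // 2
    return [(max(c - half, 0), min(c - half + w, row.size)) for c in centers]


def detect_jpeaks(
    segment: np.ndarray,
    windows: list[tuple[int, int]],
    fs: float,
    config: DetectionConfig = DEFAULT_DETECTION,
    offset: int = 0,
    segment_id: str = "",
) -> BeatAnnotation:
    """Label J-peaks inside candidate heartbeat windows.

    One candidate per window: the sample of maximum signed value (earliest
    wins a tie).  The amplitude threshold is the mean of |segment| over the
    union of all candidate windows ("abs_mean", default) or the mean of the
    per-window maxima ("window_max_mean"); candidates below it are
    rejected.  Survivors are accepted greedily in time order, dropping any
    candidate closer than the refractory spacing to the last accepted beat.
    ``offset`` shifts indices/times into whole-recording coordinates when
    the segment is a slice of a longer recording.
    """
    segment = np.asarray(segment, dtype=float)
    if not windows:
        return BeatAnnotation.empty()

    cand_idx, cand_amp = [], []
    union = np.zeros(segment.size, dtype=bool)
    for start, end in windows:
        if not 0 <= start < end <= segment.size:
            raise ValueError(f"window [{start}, {end}) outside segment")
        union[start:end] = True
        k = start + int(np.argmax(segment[start:end]))
        cand_idx.append(k)
        cand_amp.append(segment[k])

    if config.threshold_rule == "abs_mean":
        threshold = float(np.abs(segment[union]).mean())
    else:
        threshold = float(np.mean(cand_amp))

    order = np.argsort(cand_idx)
    min_gap = config.min_spacing_s
    accepted_idx, accepted_amp = [], []
    last_t = -np.inf
    for i in order:
        if cand_amp[i] < threshold:
            continue
        t = cand_idx[i] / fs
        if t - last_t < min_gap:
            continue
        accepted_idx.append(cand_idx[i] + offset)
        accepted_amp.append(cand_amp[i])
        last_t = t

    idx = np.asarray(accepted_idx, dtype=np.int64)
    return BeatAnnotation(
        idx, idx / fs, np.asarray(accepted_amp), label="J", segment_id=segment_id
    )


def estimate_heart_rate(
    beats: BeatAnnotation,
    config: DetectionConfig = DEFAULT_DETECTION,
) -> HeartRateSummary:
    """Beat-to-beat heart rate from a J-peak annotation.

    Instantaneous rate = 60 / (J-to-J interval).  Intervals outside the
    configured bounds (defaults 40-120 bpm) are flagged invalid; the mean
    is over valid intervals only, None when fewer than 2 beats or no valid
    interval exists.
    """
    n = len(beats)
    if n < 2:
        return HeartRateSummary(np.array([]), np.array([], dtype=bool), None, n)
    rr = np.diff(beats.times)
    inst = 60.0 / rr
    lo, hi = config.hr_bounds_bpm
    valid = (inst >= lo) & (inst <= hi)
    mean = float(inst[valid].mean()) if valid.any() else None
    return HeartRateSummary(inst, valid, mean, n)
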
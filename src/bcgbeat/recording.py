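"""Core containers shared across the pipeline.

A :class:`Recording` is a uniformly sampled single-channel voltage series
(the seat-cushion ballistocardiogram after analog conditioning), and a
:class:`BeatAnnotation` is an ordered list of beat events (J-peaks in the
BCG, or reference R-peaks from a simultaneous ECG) tied to a sampling grid.
Amplitudes are in arbitrary units throughout: the analog chain's absolute
gain is unknown, and every rule downstream is scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Recording", "BeatAnnotation"]

#: Labels accepted in annotation files.
BEAT_LABELS = ("J", "R")
EVENT_LABELS = BEAT_LABELS + ("ARTIFACT_START", "ARTIFACT_END")


@dataclass(frozen=True)
class Recording:
    """Uniformly sampled single-channel voltage series.

    Parameters
    ----------
    samples
        Voltage samples, arbitrary units. At least one sample.
    fs
        Sampling rate in Hz, strictly positive.
    id
        Free-form provenance string (file stem, simulator config, ...).
    """

    samples: np.ndarray
    fs: float
    id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.isfinite(samples).all():
            raise ValueError("samples contain NaN or infinite values")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds (N / fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray, id: str | None = None) -> "Recording":
        return replace(self, samples=samples, id=self.id if id is None else id)


@dataclass(frozen=True)
class BeatAnnotation:
    """Ordered beat events on a recording's time axis.

    ``indices`` are 0-based sample indices; ``times`` are seconds
    (``indices / fs`` when produced by this package, but kept explicitly so
    annotation files round-trip without an fs).  Times must be strictly
    increasing.
    """

    indices: np.ndarray
    times: np.ndarray
    amplitudes: np.ndarray = field(default=None)  # type: ignore[assignment]
    label: str = "J"
    segment_id: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        t = np.asarray(self.times, dtype=float)
        if idx.shape != t.shape or idx.ndim != 1:
            raise ValueError("indices and times must be 1-D arrays of equal length")
        if t.size > 1 and not (np.diff(t) > 0).all():
            raise ValueError("beat times must be strictly increasing")
        if self.label not in BEAT_LABELS:
            raise ValueError(f"unknown beat label {self.label!r}")
        amp = self.amplitudes
        amp = np.full(t.size, np.nan) if amp is None else np.asarray(amp, dtype=float)
        if amp.shape != t.shape:
            raise ValueError("amplitudes must match times in length")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", amp)

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def empty(cls, label: str = "J") -> "BeatAnnotation":
        return cls(np.array([], dtype=np.int64), np.array([]), label=label)

    @classmethod
    def from_times(cls, times, fs: float, label: str = "J") -> "BeatAnnotation":
        times = np.asarray(times, dtype=float)
        return cls(np.round(times * fs).astype(np.int64), times, label=label)

    def min_spacing(self) -> float:
        """Smallest inter-beat interval in seconds (inf for < 2 beats)."""
        if len(self) < 2:
            return float("inf")
        return float(np.min(np.diff(self.times)))
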
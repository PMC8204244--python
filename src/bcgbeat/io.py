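"""CSV file formats for recordings, annotations and segment sets.

Signal CSV: header ``time_s,bcg_v`` (optional third column ``ecg_v``), one
row per sample; the sampling rate is inferred from the timestamps, which
must be uniform to within a tenth of a sample.  Annotation CSV: columns
``sample_index,time_s,label`` with labels J, R, ARTIFACT_START or
ARTIFACT_END (beat rows may carry an ``amplitude`` column).  Segment CSV:
``start_sample,end_sample,start_s,end_s,duration_s``, half-open sample
intervals.  All indices are 0-based; floats are written at fixed precision
so files round-trip byte-identically.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .recording import BeatAnnotation, Recording
from .segment import SegmentSet

__all__ = [
    "DataError",
    "read_signal",
    "write_signal",
    "read_annotations",
    "write_annotations",
    "read_segments",
    "write_segments",
]


class DataError(ValueError):
    """Malformed input data (distinct from usage errors for CLI exit codes)."""


def read_signal(path) -> Recording:
    """Read a two/three-column signal CSV into a :class:`Recording`."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise DataError(f"{path}: empty signal file")
    if "time_s" not in df or "bcg_v" not in df:
        raise DataError(f"{path}: expected columns time_s and bcg_v")
    t = df["time_s"].to_numpy(dtype=float)
    x = df["bcg_v"].to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(x) | ~np.isfinite(t))[0]
    if bad.size:
        raise DataError(f"{path}: NaN or non-finite sample at row {bad[0] + 2}")
    if t.size < 2:
        raise DataError(f"{path}: need at least 2 samples to infer fs")
    dt = np.diff(t)
    fs = 1.0 / np.median(dt)
    jitter = np.abs(dt - 1.0 / fs) * fs
    worst = int(np.argmax(jitter))
    if jitter[worst] >= 0.1:
        raise DataError(
            f"{path}: non-uniform sampling at row {worst + 3} "
            f"(dt={dt[worst]:.6f} s vs expected {1.0 / fs:.6f} s)"
        )
    return Recording(x, fs, id=path.stem)


def write_signal(recording: Recording, path, ecg: np.ndarray | None = None) -> None:
    path = Path(path)
    cols = {"time_s": recording.times, "bcg_v": recording.samples}
    if ecg is not None:
        cols["ecg_v"] = np.asarray(ecg, dtype=float)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def read_annotations(path, label: str | None = None, n_samples: int | None = None) -> BeatAnnotation:
    """Read a beat annotation CSV (optionally filtering to one label)."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("sample_index", "time_s", "label"):
        if col not in df:
            raise DataError(f"{path}: missing column {col}")
    unknown = set(df["label"]) - {"J", "R", "ARTIFACT_START", "ARTIFACT_END"}
    if unknown:
        raise DataError(f"{path}: unknown labels {sorted(unknown)}")
    if label is not None:
        df = df[df["label"] == label]
    elif set(df["label"]) == {"J", "R"}:
        raise DataError(f"{path}: mixed beat labels; pass label='J' or 'R'")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size > 1 and not (np.diff(t) > 0).all():
        raise DataError(f"{path}: beat times not strictly increasing (duplicates?)")
    idx = df["sample_index"].to_numpy(dtype=np.int64)
    if n_samples is not None and idx.size and (idx.min() < 0 or idx.max() >= n_samples):
        raise DataError(f"{path}: sample index outside recording of {n_samples} samples")
    amp = df["amplitude"].to_numpy(dtype=float) if "amplitude" in df else None
    use_label = label if label is not None else (df["label"].iloc[0] if len(df) else "J")
    return BeatAnnotation(idx, t, amp, label=use_label)


def write_annotations(beats: BeatAnnotation, path, extra_events=()) -> None:
    """Write beats (plus optional (time_s, label) events) to annotation CSV."""
    rows = [
        {"sample_index": int(i), "time_s": t, "label": beats.label, "amplitude": a}
        for i, t, a in zip(beats.indices, beats.times, beats.amplitudes)
    ]
    for t, lab in extra_events:
        rows.append({"sample_index": -1, "time_s": t, "label": lab, "amplitude": np.nan})
    df = pd.DataFrame(rows, columns=["sample_index", "time_s", "label", "amplitude"])
    df.to_csv(path, index=False, float_format="%.6f")


def write_segments(segments: SegmentSet, path) -> None:
    fs = segments.fs
    pd.DataFrame(
        [
            {
                "start_sample": s,
                "end_sample": e,
                "start_s": s / fs,
                "end_s": e / fs,
                "duration_s": (e - s) / fs,
            }
            for s, e in segments.intervals
        ],
        columns=["start_sample", "end_sample", "start_s", "end_s", "duration_s"],
    ).to_csv(path, index=False, float_format="%.6f")


def read_segments(path, n_samples: int, fs: float, min_duration_s: float = 5.0) -> SegmentSet:
    df = pd.read_csv(path)
    intervals = tuple(
        (int(s), int(e)) for s, e in zip(df["start_sample"], df["end_sample"])
    )
    return SegmentSet(intervals, n_samples, fs, min_duration_s)
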
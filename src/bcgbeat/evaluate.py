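"""Scoring detected beats against reference annotations, SNR estimation,
and cohort summaries.

Beat matching is greedy, chronological and one-to-one.  Against ECG
R-peaks a detection matches the earliest unmatched reference whose latency
J - R falls in a physiologic window (default [0.05, 0.45] s: pre-ejection
plus pulse-transit delay, bounded by the 400 ms beat window); against
simulator J truth a symmetric |delta| <= 75 ms window is used.  Unmatched
detections are false positives, unmatched references undetected beats, so
TP + undetected = reference count and TP + FP = detection count on every
run.

SNR uses the subensemble-average method: E1 is the mean of the beat-aligned
400 ms windows in the first 10 s of signal, E2 the same for the next 10 s.
Coherent beat energy survives both averages while noise does not, so

    SNR_dB = 10 log10( P_s / P_n ),
    P_s = (1/N) sum E1[n] E2[n],        (cross-moment: signal power)
    P_n = (1/2N) sum (E1[n] - E2[n])^2  (difference: residual noise power)

P_n = 0 (identical averages) reports +inf; P_s <= 0 means no coherent beat
and is an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .recording import BeatAnnotation

__all__ = [
    "MatchRule",
    "MatchResult",
    "SNREstimate",
    "CohortSummary",
    "R_REFERENCE_RULE",
    "J_TRUTH_RULE",
    "match_beats",
    "accuracy_percent",
    "subensemble_average",
    "estimate_snr",
    "snr_for_recording",
    "cohort_summary",
    "load_reference_table",
]


@dataclass(frozen=True)
class MatchRule:
    """Allowed latency of a detection relative to its reference beat.

    A detection at time d matches reference r when lo <= d - r <= hi.
    """

    lo_s: float
    hi_s: float

    def __post_init__(self) -> None:
        if not self.lo_s < self.hi_s:
            raise ValueError("matching window must have lo < hi")


#: Detected J vs ECG R reference: J trails R by pre-ejection + transit delay.
R_REFERENCE_RULE = MatchRule(0.05, 0.45)
#: Detected J vs simulator J truth: symmetric tolerance.
J_TRUTH_RULE = MatchRule(-0.075, 0.075)


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    undetected: int
    pairs: tuple[tuple[float, float], ...]  # (reference time, detected time)
    rule: MatchRule

    @property
    def n_reference(self) -> int:
        return self.tp + self.undetected

    @property
    def n_detected(self) -> int:
        return self.tp + self.fp


def _times(beats) -> np.ndarray:
    t = beats.times if isinstance(beats, BeatAnnotation) else np.asarray(beats, float)
    if t.size > 1 and not (np.diff(t) > 0).all():
        raise ValueError("annotation times must be sorted strictly increasing")
    return t


def match_beats(detected, reference, rule: MatchRule = R_REFERENCE_RULE) -> MatchResult:
    """Greedy chronological one-to-one matching of detections to references."""
    det = _times(detected)
    ref = _times(reference)
    pairs: list[tuple[float, float]] = []
    fp = 0
    i = 0
    for d in det:
        # references too old for this (and every later) detection are missed
        while i < ref.size and d - ref[i] > rule.hi_s:
            i += 1
        if i < ref.size and rule.lo_s <= d - ref[i] <= rule.hi_s:
            pairs.append((float(ref[i]), float(d)))
            i += 1
        else:
            fp += 1
    tp = len(pairs)
    return MatchResult(tp, fp, ref.size - tp, tuple(pairs), rule)


def _round_half_away(x: float, decimals: int) -> float:
    scale = 10**decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def accuracy_percent(tp: int, n_reference: int) -> float:
    """Detection accuracy: 100 * TP / references, one decimal (half away)."""
    if n_reference <= 0:
        raise ValueError("reference beat count must be positive")
    return _round_half_away(100.0 * tp / n_reference, 1)


def subensemble_average(
    samples: np.ndarray,
    fs: float,
    beats,
    span: tuple[float, float],
    window_s: float = 0.400,
) -> np.ndarray:
    """Mean of beat-aligned windows whose beat lies in ``span`` seconds.

    Windows are centred on each beat and must fit entirely inside the
    signal; at least 2 beats are required for an average.
    """
    samples = np.asarray(samples, dtype=float)
    t = _times(beats)
    w = int(round(window_s * fs))
    half = w // 2
    rows = []
    for bt in t:
        if not span[0] <= bt < span[1]:
            continue
        i = int(round(bt * fs))
        if i - half < 0 or i - half + w > samples.size:
            continue
        rows.append(samples[i - half : i - half + w])
    if len(rows) < 2:
        raise ValueError(
            f"span [{span[0]}, {span[1]}) s holds {len(rows)} usable beats; "
            "need at least 2 for a subensemble average"
        )
    return np.mean(rows, axis=0)


@dataclass(frozen=True)
class SNREstimate:
    e1: np.ndarray
    e2: np.ndarray
    snr_db: float  # +inf sentinel when the averages are identical

    @property
    def n(self) -> int:
        return self.e1.size


def estimate_snr(e1: np.ndarray, e2: np.ndarray) -> float:
    """SNR in dB from two independent subensemble averages."""
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if e1.shape != e2.shape or e1.ndim != 1 or e1.size < 1:
        raise ValueError("subensemble averages must be equal-length 1-D arrays")
    p_signal = float(np.mean(e1 * e2))
    p_noise = float(np.mean((e1 - e2) ** 2) / 2.0)
    if p_noise == 0.0:
        return math.inf
    if p_signal <= 0.0:
        raise ValueError(
            "non-positive cross-moment: the two averages share no coherent beat"
        )
    return 10.0 * math.log10(p_signal / p_noise)


def snr_for_recording(
    samples: np.ndarray,
    fs: float,
    beats,
    spans: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 10.0), (10.0, 20.0)),
    window_s: float = 0.400,
) -> SNREstimate:
    """Subensemble-average SNR over two consecutive spans (default 10 s each)."""
    e1 = subensemble_average(samples, fs, beats, spans[0], window_s)
    e2 = subensemble_average(samples, fs, beats, spans[1], window_s)
    return SNREstimate(e1, e2, estimate_snr(e1, e2))


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level aggregate of per-recording results.

    ``pooled_accuracy_percent`` is 100 * sum(TP) / sum(references) over the
    included recordings (two decimals); means and SDs are over the included
    per-recording values (population SD, matching the printed footnotes of
    the study cohort this mirrors).
    """

    accuracy_mean: float
    accuracy_sd: float
    pooled_accuracy_percent: float
    pooled_tp: int
    pooled_reference: int
    snr_mean_db: float | None
    snr_sd_db: float | None
    n_recordings: int


def cohort_summary(results: pd.DataFrame, exclude=()) -> CohortSummary:
    """Aggregate a per-recording results table.

    ``results`` needs columns ``true_positives`` and ``total_r_peaks``
    (reference counts) plus either ``accuracy_percent`` or enough to derive
    it; ``snr_db`` and an identifier column (index or ``participant_id``)
    are optional.  ``exclude`` lists identifiers to drop (e.g. outlier
    recordings) before pooling.
    """
    df = results.copy()
    ids = df["participant_id"] if "participant_id" in df else pd.Series(df.index)
    keep = ~ids.isin(list(exclude)).to_numpy()
    df = df.loc[keep]
    if df.empty:
        raise ValueError("all recordings excluded from cohort summary")
    if "accuracy_percent" not in df:
        df["accuracy_percent"] = [
            accuracy_percent(tp, n)
            for tp, n in zip(df["true_positives"], df["total_r_peaks"])
        ]
    acc = df["accuracy_percent"].to_numpy(dtype=float)
    tp = int(df["true_positives"].sum())
    ref = int(df["total_r_peaks"].sum())
    snr = df["snr_db"].to_numpy(dtype=float) if "snr_db" in df else None
    return CohortSummary(
        accuracy_mean=_round_half_away(float(acc.mean()), 1),
        accuracy_sd=_round_half_away(float(acc.std(ddof=0)), 1),
        pooled_accuracy_percent=_round_half_away(100.0 * tp / ref, 2),
        pooled_tp=tp,
        pooled_reference=ref,
        snr_mean_db=None if snr is None else _round_half_away(float(snr.mean()), 1),
        snr_sd_db=None if snr is None else _round_half_away(float(snr.std(ddof=0)), 1),
        n_recordings=len(df),
    )


def load_reference_table(name: str) -> pd.DataFrame:
    """Load a bundled reference cohort table.

    ``name`` is ``"segments"`` (per-activity segment statistics of the
    reference cohort) or ``"detection"`` (per-participant J-peak detection
    performance and SNR).
    """
    fname = {"segments": "table2.csv", "detection": "table3.csv"}.get(name)
    if fname is None:
        raise ValueError(f"unknown reference table {name!r}")
    with resources.files("bcgbeat.data").joinpath(fname).open("r") as fh:
        return pd.read_csv(fh)
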
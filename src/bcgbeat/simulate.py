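"""Seeded synthetic ballistocardiogram (BCG) generator.

The seat-cushion prototype this package targets deposited no raw
recordings, so everything downstream is exercised against a simulator that
emulates the essential features of its output: a train of ~400 ms beat
complexes whose dominant positive deflection is the J-wave, placed at
RR intervals with Gaussian jitter; a paired ECG R-peak ground truth at a
fixed R-to-J latency; broadband sensor noise; slow baseline drift; and
high-amplitude motion-artifact bursts that swamp the cardiac signal, as
happens when the seated person moves.

The beat complex is a sum of five Gaussian bumps (analogues of the H, I,
J, K, L waves of a seated BCG) with J positive and largest; the default
amplitudes are balanced so the template has essentially zero mean and its
power concentrated in the 1-10 Hz band where seated BCG energy lives.

All randomness flows from the integer seed in :class:`SimConfig`; the same
config produces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import BeatAnnotation, Recording

__all__ = [
    "BeatTemplate",
    "SimConfig",
    "GroundTruth",
    "DEFAULT_TEMPLATE",
    "make_beat_template",
    "simulate_recording",
    "inject_artifacts",
]


@dataclass(frozen=True)
class BeatTemplate:
    """Parametric one-beat BCG waveform: Gaussian bumps around the J-wave.

    Offsets are milliseconds relative to the J-peak, amplitudes are
    dimensionless (J = +1 and largest in magnitude), widths are Gaussian
    sigmas in ms.  Total support is the length of the sampled waveform and
    may not exceed 400 ms — the typical duration of one seated-BCG beat
    complex.
    """

    offsets_ms: tuple[float, ...] = (-110.0, -55.0, 0.0, 65.0, 130.0)
    amplitudes: tuple[float, ...] = (0.30, -0.70, 1.00, -0.80, 0.155)
    widths_ms: tuple[float, ...] = (22.0, 20.0, 20.0, 20.0, 22.0)
    support_ms: float = 400.0

    def __post_init__(self) -> None:
        if not len(self.offsets_ms) == len(self.amplitudes) == len(self.widths_ms):
            raise ValueError("offsets, amplitudes and widths must have equal length")
        if self.support_ms <= 0 or self.support_ms > 400.0:
            raise ValueError("template support must be in (0, 400] ms")
        amps = np.asarray(self.amplitudes)
        if amps.size == 0 or np.all(amps == 0):
            raise ValueError("degenerate template: all amplitudes are zero")
        j = int(np.argmax(np.abs(amps)))
        if amps[j] <= 0 or self.offsets_ms[j] != 0.0:
            raise ValueError(
                "the largest-magnitude wave must be the positive J-wave at offset 0"
            )
        if any(w <= 0 for w in self.widths_ms):
            raise ValueError("wave widths must be positive")


DEFAULT_TEMPLATE = BeatTemplate()


def make_beat_template(template: BeatTemplate = DEFAULT_TEMPLATE, fs: float = 250.0) -> np.ndarray:
    """Sample a :class:`BeatTemplate` onto a uniform grid.

    Returns a waveform of ``round(support_ms/1000 * fs)`` samples centred on
    the J-wave; the global maximum of the returned array is the J sample.
    """
    if not fs > 0:
        raise ValueError(f"fs must be positive, got {fs}")
    n = int(round(template.support_ms / 1000.0 * fs))
    if n < 1:
        raise ValueError("fs too low: template support shorter than one sample")
    t_ms = (np.arange(n) - n // 2) / fs * 1000.0
    w = np.zeros(n)
    for off, amp, sd in zip(template.offsets_ms, template.amplitudes, template.widths_ms):
        w += amp * np.exp(-0.5 * ((t_ms - off) / sd) ** 2)
    if int(np.argmax(w)) != n // 2:
        raise ValueError("template's global maximum is not the J-wave sample")
    return w


@dataclass(frozen=True)
class SimConfig:
    """Knobs for one simulated recording.

    Heart rate is bounded to the physiologic analysis band [40, 120] bpm;
    jitter is kept below a quarter of the mean RR so beats never collide.
    Noise SD is relative to the J amplitude (which is 1 by construction).
    Artifacts are (start_s, duration_s, amplitude multiplier) bursts.
    """

    duration_s: float = 60.0
    fs: float = 250.0
    mean_hr_bpm: float = 60.0
    rr_jitter_sd_s: float = 0.03
    r_to_j_latency_s: float = 0.20
    noise_sd: float = 0.10
    drift_amplitude: float = 0.30
    drift_freq_hz: float = 0.15
    artifacts: tuple[tuple[float, float, float], ...] = ()
    seed: int = 0
    template: BeatTemplate = field(default=DEFAULT_TEMPLATE)

    def __post_init__(self) -> None:
        if not 40.0 <= self.mean_hr_bpm <= 120.0:
            raise ValueError("mean heart rate must lie in [40, 120] bpm")
        if self.fs < 50.0:
            raise ValueError("fs must be at least 50 Hz")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        mean_rr = 60.0 / self.mean_hr_bpm
        if not self.rr_jitter_sd_s < mean_rr / 4:
            raise ValueError("RR jitter SD must be below mean RR / 4")
        if self.drift_freq_hz >= 0.3:
            raise ValueError("baseline drift must stay below 0.3 Hz")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise and drift amplitudes must be non-negative")
        _validate_schedule(self.artifacts, self.duration_s)

    @property
    def mean_rr_s(self) -> float:
        return 60.0 / self.mean_hr_bpm


def _validate_schedule(schedule, duration_s: float) -> None:
    prev_end = -np.inf
    for start, dur, mult in sorted(schedule):
        if dur <= 0:
            raise ValueError("artifact duration must be positive")
        if start < 0 or start + dur > duration_s + 1e-9:
            raise ValueError(
                f"artifact interval [{start}, {start + dur}] s outside recording"
            )
        if mult < 1:
            raise ValueError("artifact amplitude multiplier must be >= 1")
        if start < prev_end:
            raise ValueError("artifact intervals overlap")
        prev_end = start + dur


@dataclass(frozen=True)
class GroundTruth:
    """Simulator truth channel: true beat times and artifact intervals."""

    j_times: np.ndarray
    r_times: np.ndarray
    artifact_intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        j = np.asarray(self.j_times, dtype=float)
        r = np.asarray(self.r_times, dtype=float)
        if j.shape != r.shape:
            raise ValueError("J and R lists must have the same length")
        for arr in (j, r):
            if arr.size > 1 and not (np.diff(arr) > 0).all():
                raise ValueError("beat times must be strictly increasing")
        object.__setattr__(self, "j_times", j)
        object.__setattr__(self, "r_times", r)

    def j_annotation(self, fs: float) -> BeatAnnotation:
        return BeatAnnotation.from_times(self.j_times, fs, label="J")

    def r_annotation(self, fs: float) -> BeatAnnotation:
        return BeatAnnotation.from_times(self.r_times, fs, label="R")


def _draw_beat_times(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """J-peak times: first beat after a short lead-in, then jittered RRs.

    Jitter is truncated at +-3 SD so the instantaneous rate stays inside a
    narrow band around the configured mean.
    """
    mean_rr = cfg.mean_rr_s
    half_support = cfg.template.support_ms / 2000.0
    t = cfg.r_to_j_latency_s + half_support + 0.05
    last_valid = cfg.duration_s - half_support
    times = []
    while t <= last_valid + 1e-12:
        times.append(t)
        rr = mean_rr
        if cfg.rr_jitter_sd_s > 0:
            rr += float(np.clip(rng.normal(0.0, cfg.rr_jitter_sd_s),
                                -3 * cfg.rr_jitter_sd_s, 3 * cfg.rr_jitter_sd_s))
        t += rr
    if not times:
        raise ValueError("duration too short to contain a single beat")
    return np.asarray(times)


def simulate_recording(cfg: SimConfig) -> tuple[Recording, GroundTruth]:
    """Render one annotated recording from a :class:`SimConfig`.

    Beat templates are placed at J times drawn from the RR model, then
    baseline drift, white noise and scheduled artifact bursts are added.
    Identical configs (including seed) produce bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    wave = make_beat_template(cfg.template, cfg.fs)
    half = len(wave) // 2

    j_times = _draw_beat_times(cfg, rng)
    x = np.zeros(n)
    for tj in j_times:
        i0 = int(round(tj * cfg.fs)) - half
        seg = slice(max(i0, 0), min(i0 + len(wave), n))
        x[seg] += wave[seg.start - i0 : seg.stop - i0]

    if cfg.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / cfg.fs
        x += cfg.drift_amplitude * np.sin(2 * np.pi * cfg.drift_freq_hz * t + phase)
    if cfg.noise_sd > 0:
        x += rng.normal(0.0, cfg.noise_sd, n)

    rec = Recording(x, cfg.fs, id=f"sim-seed{cfg.seed}-hr{cfg.mean_hr_bpm:g}")
    if cfg.artifacts:
        rec = inject_artifacts(rec, cfg.artifacts, rng=rng)

    truth = GroundTruth(
        j_times=j_times,
        r_times=j_times - cfg.r_to_j_latency_s,
        artifact_intervals=tuple((s, s + d) for s, d, _ in cfg.artifacts),
    )
    return rec, truth


def _bandlimited_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD noise confined to the 1-10 Hz band where BCG power lives."""
    white = rng.normal(0.0, 1.0, n + int(fs))  # pad to flush filter transients
    sos = sps.butter(4, [1.0, 10.0], btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfilt(sos, white)[int(fs):]
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def inject_artifacts(
    recording: Recording,
    schedule,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Add motion-artifact bursts to a recording.

    Each (start_s, duration_s, multiplier) entry adds band-limited noise
    scaled to ``multiplier`` times the clean-signal SD, with raised-cosine
    on/off ramps (10% of the burst, capped at 0.25 s — movement onsets are
    sub-second) so there is no step discontinuity.  Samples outside the
    scheduled intervals are untouched.
    """
    schedule = tuple(schedule)
    _validate_schedule(schedule, recording.duration)
    if not schedule:
        return recording
    if rng is None:
        rng = np.random.default_rng(seed)

    x = recording.samples.copy()
    fs = recording.fs
    inside = np.zeros(recording.n, dtype=bool)
    spans = []
    for start, dur, mult in schedule:
        i0 = int(round(start * fs))
        i1 = min(int(round((start + dur) * fs)), recording.n)
        inside[i0:i1] = True
        spans.append((i0, i1, mult))
    clean_sd = x[~inside].std() if (~inside).any() else x.std()
    if clean_sd == 0:
        clean_sd = 1.0

    for i0, i1, mult in spans:
        m = i1 - i0
        burst = _bandlimited_noise(m, fs, rng) * mult * clean_sd
        ramp = max(min(int(round(0.1 * m)), int(round(0.25 * fs))), 1)
        window = np.ones(m)
        edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        window[:ramp] = edge
        window[-ramp:] = edge[::-1]
        x[i0:i1] += burst * window
    return recording.with_samples(x)
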
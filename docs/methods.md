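# Methods

## Signal model and scope

The package operates on a single-channel, uniformly sampled voltage series
assumed to be the output of an analog-conditioned load-cell bridge under a
seated person: a train of ~400 ms ballistocardiographic beat complexes
whose dominant positive deflection (the J-wave) marks each heartbeat,
superimposed on baseline drift, broadband sensor noise, and intermittent
high-amplitude excursions caused by voluntary movement. Amplitudes are
treated as arbitrary units throughout — the analog gain is unknown and
every decision rule in the pipeline is scale-invariant. The analog
front-end itself (bridge excitation, amplification, anti-alias filtering)
is out of scope; so are respiratory modulation, heart-rate variability
analysis, and any ECG-assisted detection.

No raw recordings accompany the method this package implements, so the
sampling rate of the original acquisition is unknown. The canonical
configuration is fs = 250 Hz — comfortably above the 15 Hz analysis band —
and every time-domain parameter is specified in seconds and converted to
samples at runtime, so nothing depends on that choice. Scale selection for
the wavelet stage is exposed as a pseudo-frequency (see below) for the
same reason.

## Preprocessing

Bandpass 0.5–15 Hz, 4th-order Butterworth, applied forward–backward
(`sosfiltfilt`) so the response is zero-phase: beat *timing* is the
quantity everything downstream consumes, and a causal filter would shift
it by a frequency-dependent group delay. Reflective padding of one
approximate impulse-response length (3·fs/low ≈ 6 s at the defaults,
clipped to the record length) suppresses startup transients at the record
edges. Only the band itself is inherited from the acquisition design; the
family, order and phase handling are this package's choices and are
configurable.

## Motion-artifact segmentation

A 1 s moving windowed variance Var_mov is compared against the threshold
½·mean(Var_mov): windows above it are discarded as motion artifact, and
surviving runs shorter than 5 s are dropped (a 5 s run still holds ≥ 3
beats at the 40 bpm floor, enough for two rate intervals). The ½ factor
and both durations are configurable; ½ sits in the middle of the ¼–1
range that distinguishes movement from stillness in practice.

Two window layouts are provided. The default is a true sliding variance
(hop = 1 sample, computed from cumulative sums); a non-overlapping "tiled"
layout (one window per second) is used where window-level bookkeeping at
1 s resolution is wanted, e.g. when scoring artifact recall/precision
against a simulator's schedule.

Two degenerate regimes deserve note:

* **Exactly constant variance series** — the literal rule discards every
  window (v > v/2 always); the implementation keeps the whole recording
  instead, since a spread-free series has no excursions to reject.
* **Artifact-free but noisy recordings** — every window's variance then
  sits *near* the mean, i.e. above half of it, and the literal rule again
  discards everything. This is intrinsic to a threshold tied to the
  recording's own mean: the rule presumes artifacts are present and
  sparse, inflating the mean well above the clean-window level. The
  implementation keeps the rule faithful rather than second-guessing it;
  for recordings known to be still (the protocol this pipeline mirrors
  analysed its sitting-still minute whole), segmentation is disabled via
  `PipelineConfig(segmentation_enabled=False)` / `detect --no-segmentation`.

Clean runs separated by a single discarded window are not merged
(conservative: never bridge across an artifact).

## CWT J-peak detection

The transform is W_n(s) = norm(s)·Σ_{n′} x_{n′} ψ((n′−n)/s) with the real
Morlet ψ(η) = exp(−η²/2)·cos(5η), evaluated per scale by FFT convolution
with the kernel truncated at |η| ≤ 8 (|ψ| < 1e-13 there); the fast path is
verified against the direct double summation in the tests. Scales are
dimensionless sample counts; the pseudo-frequency of scale s is Fc·fs/s
with Fc ≈ 0.8125 for this wavelet, so the analysis scale is derived from a
frequency: the default 6.77 Hz gives scale 30 at fs = 250 Hz and transfers
correctly to any other rate. `norm(s) = 1/√s` (energy normalization) by
default; a flag yields the bare sum — immaterial here, since only one
scale row is ever ranked at a time. Coefficients within one truncated
support of an edge are flagged as boundary-affected.

Detection then proceeds on the single analysis row:

1. Local maxima of |W| with minimum separation 400 ms and height ≥ the
   row's mean magnitude become heartbeat-window centres; each window spans
   ±200 ms around its centre, clipped to the segment.
2. The J-candidate of a window is its maximum *signed* sample (the J-wave
   is the dominant positive deflection; ties go to the earliest sample).
3. Candidates must clear an amplitude threshold. "Mean of all heartbeat
   segments" is ambiguous for a zero-mean signal, so the default reading
   is the mean of |x| over the union of candidate windows; a variant using
   the mean of per-window maxima is selectable but would by construction
   reject about half of the true beats.
4. Survivors are accepted greedily in time order with a 500 ms refractory
   period (threshold first, then spacing). The refractory bound is what
   caps the detectable rate at 120 bpm.

Instantaneous heart rate is 60/RR per accepted beat pair; intervals
implying rates outside [40, 120] bpm are flagged invalid and excluded from
the mean, which is `None` (never 0) when fewer than two beats or no valid
interval exists.

## Evaluation

Matching is greedy, chronological and one-to-one. Against ECG R-peaks a
detection matches the earliest unmatched reference with J−R ∈
[0.05, 0.45] s (physiologic pre-ejection plus transit delay, bounded by
the beat-window length); against simulator J truth, |Δ| ≤ 75 ms. The
conservation identities TP + undetected = #references and TP + FP =
#detections hold on every run by construction. Accuracy is 100·TP/refs
rounded half-away-from-zero to one decimal; pooled cohort accuracy
(Σ TP / Σ refs) is reported to two decimals, and cohort SDs are population
SDs (matching the convention of the bundled reference tables).

The SNR estimator is the subensemble cross-correlation form: E1 and E2 are
beat-aligned 400 ms window averages over two consecutive 10 s spans, and

    SNR = 10·log10( P_s / P_n ),   P_s = (1/N) Σ E1·E2,
                                   P_n = (1/2N) Σ (E1 − E2)²,

i.e. coherent beat energy as the cross-moment of two independent averages,
residual noise as half their mean squared difference. P_n = 0 (identical
averages) returns +∞; P_s ≤ 0 means the spans share no coherent beat and
raises. The printed form of this estimator in the acquisition study this
mirrors is not machine-readable; the formula above is taken from the
ensemble-averaging SNR literature that study cites, and is declared here
rather than inferred. Alignment uses detected J-peaks (self-contained —
no ECG needed), windows centred on the beat.

Reference tables for a 20-participant seated cohort (per-activity segment
statistics; per-participant TP/FP/missed counts, accuracy and SNR) ship as
CSV fixtures for cohort-arithmetic checks. In those printed tables a few
rows have TP + undetected < total R-peaks (an unstated edge-beat
convention of the original visual adjudication); the implementation always
enforces the conservation identity on its own outputs and uses the printed
columns as-is when aggregating.

## Synthetic data

The simulator is the package's test bed and defines the conditions under
which the pipeline's claims are verified:

* **Beat template** — five Gaussian bumps (H, I, J, K, L analogues) at
  −110/−55/0/+65/+130 ms with amplitudes +0.30/−0.70/+1.00/−0.80/+0.155
  and σ 22/20/20/20/22 ms, sampled over a 400 ms support. The amplitudes
  are balanced so the template mean is < 0.01% of the J amplitude (a
  band-limited signal has no DC) and ~95% of a clean beat train's power
  falls in 1–10 Hz, where seated-BCG energy concentrates. The shape is a
  plausible morphology, not a fit to any participant.
* **RR model** — RR = 60/HR + Gaussian jitter truncated at ±3 SD (default
  SD 30 ms, a typical resting short-term variability); no respiratory
  modulation. Mean HR is bounded to [40, 120] bpm, jitter to < RR/4.
* **R-to-J latency** — fixed 200 ms (typical pre-ejection period plus
  pulse transit), configurable; the J and R truth channels differ by
  exactly this latency.
* **Noise and drift** — white Gaussian noise (default SD = 10% of the J
  amplitude) and a sub-0.3 Hz sinusoidal baseline (default 0.15 Hz,
  amplitude 0.3) that the bandpass removes.
* **Artifacts** — scheduled bursts of 1–10 Hz band-limited noise scaled to
  a multiple (≥ 1) of the clean-signal SD, added with raised-cosine on/off
  ramps of 10% of the burst length capped at 0.25 s. The cap reflects that
  voluntary-movement onsets are sub-second; without it a long burst's
  multi-second fade-in defeats any 1 s-resolution variance detector at its
  edges.

Everything is driven by one integer seed; identical configs are
bit-identical. What the simulator does *not* emulate — posture and
body-mass dependence of the waveform, inter-subject morphology differences,
non-stationary noise, beats overlapping artifacts' tails — bounds what
passing tests show: they validate the algorithmic pipeline under the
stated model, not clinical performance on human recordings.

## Numerical and interface choices

Sample indices are 0-based, intervals half-open, times in seconds; CSVs
carry both `sample_index` and `time_s` so files are unambiguous without an
fs. Signal CSV timestamps must be uniform to within 0.1 sample. Floats are
serialized at fixed precision so reports and files round-trip
byte-identically. CLI exit codes: 0 success, 1 usage error, 2 data error.
Problem sizes in the test and acceptance runs (twenty 60 s recordings for
detection recovery, three 300 s recordings for segmentation recovery, 2 s
signals for the brute-force CWT oracle) keep the full suite in a few
seconds while leaving every statistical margin wide.

## Known limitations

* The ½·mean variance rule cannot segment an artifact-free recording (see
  above); callers must know when to disable it.
* Detection assumes the J-wave is the largest positive deflection; signals
  where it is not (low-SNR subjects in the reference cohort) degrade
  accuracy, which is exactly the failure mode the cohort's three outliers
  exhibit.
* The refractory period makes rates above 120 bpm undetectable by design.
* SNR requires ≥ 2 usable beats in each 10 s span and a positive
  cross-moment; recordings failing either report no SNR rather than a
  number.
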
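# Methods

## Signal model and segmentation

Input is triaxial acceleration in m/s² sampled uniformly at a nominal
40 Hz. All detectors operate on non-overlapping 3.2-s windows (128 samples
at 40 Hz) tiled from sample 0; a trailing remainder shorter than one
window is discarded. The segment grid is anchored to the recording start,
not to wall-clock minute boundaries, and a segment belongs to the minute
and 10-min period containing its start sample. Periods are half-open
[start, start + 10 min).

Spectra are single-taper Hann periodograms per segment. Each binned
spectrum is rescaled so its total equals the time-domain variance of the
mean-removed signal: the Hann window otherwise biases total power by the
window's energy ratio (~15 % RMS scatter at N = 128 for noise-like
segments), and the rescaling makes band powers over any partition of the
spectrum sum exactly to the signal variance while leaving relative
spectral shape untouched. DC is excluded, so every spectral quantity is
invariant to constant per-channel offsets — this is the only gravity /
orientation handling; no calibration is attempted.

Walk-classifier features: log band powers over 8 roughly log-spaced bands
covering 0–15 Hz, per channel plus the magnitude of the mean-removed
acceleration vector — 32 features per segment. The band edges are
config-controlled (`featbank`); models refuse to score features produced
under a different bank (a hash of `fs`, `window_s` and the edges travels
with the model).

## Walk detection

RBF-kernel SVM, C = 1, γ = 1/n_features, class-balanced, preceded by
feature standardisation. The model is trained once on a labelled corpus
and frozen; per-patient runs only score with it. Training reserves a
stratified 25 % held-out split whose accuracy / sensitivity / specificity
are stored in the model metadata. Hyperparameters are deliberately not
tuned per run: a fixed, subject-independent detector is part of the
design contract, and on the synthetic corpus the fixed settings already
hold all three held-out metrics above 0.9.

A walking bout is a maximal run of consecutive walking segments; isolated
single walking segments count as bouts of one window.

## Stride detection and fluidity

Within a bout the three channels are low-pass filtered (4th-order
Butterworth at 10 Hz, zero-phase). Initial contacts are local minima of
the gravity-dominant (vertical) channel, at least 0.4 s apart and with
prominence above half the channel's standard deviation, that coincide
within 0.1 s with a local extremum on both other channels. A stride spans
alternate contacts (two steps); strides outside 0.4–2.4 s are dropped, and
the first two and last two strides of every bout are discarded to avoid
gait initiation and termination, so a bout with k detected strides emits
max(0, k − 4).

Fluidity maps the stride's 0–10 Hz spectrum to one scalar on the m/s²
scale: `sqrt(P_harm / P_band) * RMS`, where P_band is the stride's total
0–10 Hz power, P_harm the power within ±0.45 f₀ of the first two
harmonics of the stride fundamental f₀ = 2/duration (step frequency), and
RMS the root of the summed per-channel variances. The functional is
homogeneous of degree 1 in amplitude, zero for silent strides, and ranks
harmonically simple (fluent) strides above jerky multi-harmonic strides
of equal energy. Short strides make the harmonic windows wide relative to
spectral resolution (the stride is zero-padded to 1024 points), so the
absolute fluidity value under-shoots the ideal closed form; both gait
classes shrink together and the separation the thresholding relies on is
preserved.

## Patient threshold and gait classification

All of a patient's stride fluidities (minimum 30; below that every period
is indeterminate) feed a Gaussian KDE with Silverman bandwidth, evaluated
on a 512-point grid — a smoothed realisation of the fluidity histogram
that makes the mode rules computable. Modes are local density maxima with
basins delimited by the density minima between them. If at least two
modes hold ≥ 15 % of the data each, θ is the midpoint of the two
highest-density qualifying modes (*bimodal-midpoint*). Otherwise θ is the
point left of the global mode where the density falls to 60 % of the
peak, linearly interpolated between grid points (*submode-shoulder*); for
a Gaussian this sits at mode − σ·√(−2 ln 0.6) ≈ mode − 1.01 σ, which the
tests verify. θ is clipped to the observed fluidity range.

Classification per period: mean fluidity below θ − 1.7 m/s² is
bradykinetic, above θ + 1.7 m/s² normal, within ±1.7 m/s² intermediate;
periods without strides are indeterminate. Low fluidity meaning
bradykinesia is the clinically coherent direction and is documented by
the config flag `bradykinesia_low_fluidity` (default true); flipping it
reverses the two outer labels.

## Dyskinesia

Gate precedence is total and exclusive: walking (SVM) first, else
postural transition when 0.1–0.6 Hz summed band power exceeds τ_pt, else
analyzable. Analyzable segments score positive when 1–4 Hz summed band
power exceeds τ_dysk. τ_pt = 0.158 and τ_dysk = 0.849 (m/s²)² are global
constants — identical for all patients — calibrated once on the synthetic
corpus by maximising Youden's J for transition-vs-other and
chorea-vs-rest respectively (seed 20220414, n = 800), then frozen in the
default config; `calibrate_band_thresholds` reproduces them.

Minute rule: < 30 % analyzable segments (denominator: all segments of the
minute) → undetermined; else > 40 % positive (denominator: analyzable
segments only) → present; else absent. Both inequalities strict. Period
rule: ≥ 8 of 10 undetermined minutes → undetermined, else majority among
determined minutes with present/absent ties resolved to absent —
conservative against over-calling dyskinesia. Minutes containing no
segments count as undetermined.

## Fusion and gap filling

Dyskinesia present forces On regardless of gait (chorea does not occur in
the Off-state). Otherwise gait decides; an undetermined dyskinesia
verdict is treated as "no dyskinesia shown" whenever gait is informative,
including the normal-gait cell, which therefore yields On. Indeterminate
gait without dyskinesia is Unknown. Gap filling slides over consecutive
period triples with stride 1 (config `triple_stride` also supports
disjoint triples, stride 3): an Unknown middle flanked by two equal known
states inherits that state and is flagged `filled`; filled values may
seed later triples. Conclusive results are periods classified On or Off.

## Diary comparison

Diaries live on a 30-min grid. Each conclusive period is paired with the
slot containing its midpoint — the natural many-to-one mapping from 10-min
outputs to 30-min slots; periods over unannotated slots, and Intermediate
/ Unknown periods, are excluded. Off is the positive class. Per-patient
metrics are displayed ×100 rounded half-up to integers; cohort means run
over patients where the metric is defined (a patient with no Off-detection
has no PPV), count columns are summed over all patients, and two derived
rates are reported: conclusive detections per monitored hour and the
percent excess of sensor detections over diary annotations. Sensitivity
and specificity are not computed: without observers, the diary does not
record all episodes, so the denominators are unknowable.

## Synthetic data

The generator renders a full day at 40 Hz as the sum of interpretable
parts, with a per-event ground-truth log sufficient to derive oracle
outputs for every stage:

* **Schedule** — piecewise-constant On/Off truth; default 8-h day of
  alternating 60-min blocks starting Off (a 50/50 fluctuating day).
* **Gait bouts** — Poisson arrivals at 0.3/min, 20–45 s long, rendered as
  harmonic stride trains with simultaneous contact extrema on all three
  channels. On-state: cadence 1.8 steps/s, power in harmonics 1–2.
  Off-state: cadence 1.2 steps/s, smaller amplitude, power pushed into
  harmonics 3–5. Per-bout amplitude is drawn from target fluidity
  N(10, 0.5²) (On) / N(2.5, 0.4²) (Off) m/s² and converted to amplitude
  through the closed-form fluidity of the harmonic mix; the targets sit
  far enough apart that the measured distributions separate by far more
  than the 3 pooled SDs the histogram thresholding needs.
* **Dyskinesia** — 1–4 Hz band-limited noise (total RMS 1.5 m/s²) added
  at rest during On blocks with duty cycle 0.5 on a 30-s tiling.
* **Postural transitions** — half-sine transients, 2.5–5 s, 2 m/s²
  vertical, 10/h, placed outside bouts.
* **Rest / sensor** — white noise (SD 0.08 m/s²) plus 9.81 m/s² gravity
  on the vertical channel.
* **Diary** — per 30-min slot, the majority true state, omitted with
  probability 0.1 and flipped with probability 0.05.

Defaults were chosen once so that each signal class is realistic for the
detectors that consume it (amplitudes and bands in the ranges the
detectors target) and are not adjusted per experiment. What the generator
does **not** model: tremor, freezing of gait, biomechanical waveform
detail beyond harmonic content, sensor drift or re-orientation, off-wrist
/ non-wear time, and diaries biased rather than merely noisy. Passing the
synthetic benchmark therefore demonstrates internal correctness of the
pipeline — each stage recovers the ground truth its input encodes — not
clinical accuracy on real patients; the bundled 23-patient reference
table is the external anchor for the validation arithmetic.

## Numerical choices and edge cases

* Periodogram energy rescaling (above) guarantees Parseval consistency to
  float precision; the white-noise partition test allows 1 %.
* Band membership is lo ≤ f < hi over periodogram bins, so a partition of
  band edges is exactly additive.
* KDE grid: 512 points spanning the data range ±3 bandwidths; 60 %
  crossing linearly interpolated.
* Zero-power strides and empty bands return 0, never NaN.
* Degenerate inputs rejected with errors: fs ≤ 0, bands with lo ≥ hi or
  beyond Nyquist, single-class or under-sized SVM training sets, periods
  without exactly 10 minutes, recordings shorter than one period.
* Problem sizes in tests and the acceptance script — 2000-segment corpus,
  one 8-h simulated day, 100 simulated patients for threshold recovery —
  were chosen as the smallest sizes at which the measured rates are
  stable across seeds.

## Known limitations

* The SVM is trained on synthetic signal classes; its perfect held-out
  separation reflects the generator's clean class structure, not expected
  field performance.
* The fluidity functional is one defensible reduction of a 0–10 Hz
  spectrum to a scalar; alternatives (e.g. spectral entropy) would need
  re-deriving the ±1.7 m/s² intermediate band.
* τ_pt and τ_dysk are calibrated on synthetic data; deploying on a real
  sensor would require re-calibration on labelled recordings.
* Recordings are assumed gap-free; gaps must be split into separate
  recordings upstream.
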
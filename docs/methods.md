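# Methods

## Measurement model

A fiber Bragg grating (FBG) taped over a pulsation point acts as a strain
sensor: arterial pulsation modulates the grating pitch Λ and hence the
reflected Bragg wavelength λ_B = 2·n_eff·Λ. The interrogator converts the
wavelength shift Δλ into an interferometric phase through a Mach–Zehnder
interferometer with optical path difference d,

    Δφ = 2π · n_eff · d / λ_B² · Δλ,

observed by three detectors at phase offsets 0, 2π/3 and 4π/3:

    V_n = α_n (C + cos(φ(t) + 2π(n−1)/3)),   n = 1, 2, 3.

After channel normalization (α_n → 1, C → 1) the quadrature identity

    √3 (V₂ − V₃) = −3 sin φ,    V₂ + V₃ − 2V₁ = −3 cos φ

holds exactly, so `demodulate_phase` evaluates `arctan2(−num, −den)` and
unwraps by continuity; the generating phase is recovered up to a global
multiple of 2π (machine precision for noiseless input, error growing
continuously with detector noise). Samples where numerator and denominator
both vanish carry no phase information and are filled by linear
interpolation; a record that is degenerate everywhere is an error.

The phase-offset index in the detector equation is the detector number, not
the refractive index: that is the only reading under which the quadrature
identity above is an identity (verified symbolically), and it is what the
three-detector layout physically means.

Channel calibration (`estimate_channel_calibration`) assumes a calibration
sweep covering at least one full fringe, taken with the sensor off the
pulsation point: the per-channel gain is half the peak-to-peak envelope and
the shared offset is the envelope midpoint. This min/max estimator is the
simplest one consistent with "amplitudes and offset adjusted to 1"; it is
bias-prone under heavy noise but the calibration sweep is a controlled,
high-SNR measurement.

### Optical constants

`BraggConfig` defaults: n_eff = 1.5, λ_B = 1550 nm (mid-band of a
1525–1570 nm ASE source), d = 3.33 mm. Whether the interferometer constant
d is the geometric fiber-length difference or the optical path (n·length) is
an instrument convention — the two differ by the factor n_eff — so d is an
explicit configuration value rather than being silently derived; 3.33 mm is
the geometric-length reading of a ~5 mm optical path at n = 1.5. One fringe
(2π) then corresponds to Δλ = λ_B²/(n_eff·d) ≈ 0.481 nm at λ_B = 1550 nm.

## Pulse-wave processing

The wavelength-shift trace approximates the acceleration pulse wave
(second derivative of the volume pulse), whose beat carries five
characteristic extrema A–E. Processing:

1. **Band-pass 0.5–5 Hz**, cascaded 4th-order Butterworth high-pass and
   low-pass corners applied forward–backward (`sosfiltfilt`). Second-order
   sections are used because a transfer-function (b, a) realization of a
   0.5 Hz corner at 10 kHz is numerically unstable. Zero-phase filtering
   preserves the relative timing of the A–E waves. Records must exceed 3 s
   (filter transients).
2. **Beat segmentation.** The beat period is estimated from the
   autocorrelation maximum within the lag range implied by 40–180 bpm;
   anchors are then positive peaks with minimum separation 0.75 of that
   period and prominence ≥ 30% of the robust amplitude (90th percentile of
   |x|). A plain fixed minimum separation of 60/max_bpm proved insufficient:
   beats with a strong early-diastolic E wave produce spurious anchors. Each
   beat window spans 30% of the median inter-peak interval before the anchor
   to 70% after; boundary-truncated windows are dropped; fewer than 3 beats
   is an error.
3. **Ensemble averaging.** Each beat is linearly resampled to L = 100
   samples with its anchor pinned at index 30 (fraction 0.3), the pointwise
   mean is taken, and the average is affinely rescaled so its minimum is
   exactly 0 and its systolic peak exactly 1. The peak ("clipping position")
   is the global maximum of the averaged beat; it must lie within a few
   samples of the alignment anchor, otherwise the beats were misaligned and
   an error is raised. Averaging before normalizing is the default;
   `normalize_each=True` switches to per-beat normalization first (the two
   differ only when beat amplitudes vary within a record).
4. **Features.** `second_derivative` (central differences) and
   `detect_peaks_ABCDE` (A = global max, then alternating local
   minima/maxima for B–E; absent extrema are reported missing, amplitudes
   measured relative to the beat mean). Clinical waveform-pattern
   classification is deliberately not provided — there is no defensible
   decision rule to encode — only the peak positions and amplitude ratios
   that such schemes are built from.

L = 100 and anchor fraction 0.3 are configuration keys; nothing downstream
assumes their values. Linear resampling (no dynamic time warping) keeps the
beat vector an affine function of the underlying waveform, which is what the
linear calibration model assumes.

## PLS1 calibration

The normalized averaged beat (L-vector) is the explanatory variable and the
cuff reference pressure (mmHg) the objective. PLS rather than principal
component regression because the reference itself carries measurement error.
The implementation is single-response NIPALS on mean-centered data without
variance scaling (beats already share the [0, 1] scale):

    w_a = X'y/‖X'y‖,  t_a = Xw_a,  p_a = X't_a/t'ₐt_a,  q_a = y't_a/t'ₐt_a,

deflating X and y each factor; the regression vector is
b = W(P'W)⁻¹q and predictions are ŷ = ȳ + (x − x̄)b. At k = rank the fit
coincides with ordinary least squares (tested against a normal-equations
oracle); the k-factor fit equals the least-squares solution restricted to
the Krylov subspace span{X'y, (X'X)X'y, …}, which is what the independent
test oracle computes.

**Factor count.** Leave-one-out PRESS is computed for k = 0 … k_max
(PRESS(0) = mean-only model; the per-fold NIPALS is evaluated incrementally
so one pass yields every k). Starting from k = 0, factor k+1 is added while
PRESS(k)/PRESS(k+1) exceeds the upper 5% critical value of F(n, n); the
first non-significant step stops the search. The comparison is between
consecutive models (not Haaland–Thomas style against the global PRESS
minimum), degrees of freedom (n, n) and α = 0.05 are configuration, and at
least one factor is always returned — a zero-factor calibration curve is
not a curve.

**Evaluation.** SEP = √(Σ(ŷ−y)²/(n−1)) in mmHg ("measurement accuracy"),
without bias removal; bias is reported separately; R is the validation-set
Pearson correlation of predicted versus reference pressure (undefined and
reported missing when either side has zero variance).

## Synthetic subjects

The generator replaces the sensor-on-wrist measurement while preserving the
statistical structure the method assumes:

- **Morphology:** one beat is a sum of five Gaussian bumps at the A–E
  positions (A positive and dominant; B, D negative; C, E positive), with
  amplitudes base + slope·(BP − BP_mean). The linear morphology–pressure
  coupling is the minimal structure that makes a linear calibration correct.
  Bump widths (0.055–0.085 of the beat period) are wide enough that the beat
  keeps ≳95% of its energy inside the 0.5–5 Hz analysis band, consistent
  with the A–E waves remaining visible after that filter.
- **Record:** templates tiled at the subject heart rate with ±3% uniform
  beat-interval jitter, scaled by phase_gain = 2.5 rad to interferometric
  phase, plus a 0.08 Hz baseline drift (amplitude 0.8 rad, removed by the
  band-pass), encoded through the three-phase model with additive Gaussian
  detector noise (default sd 0.01 on unit-amplitude channels).
- **Pressures:** latent BP per record ~ Normal(BP_mean, BP_sd); the cuff
  reference is latent + Normal(0, 2 mmHg). The 2 mmHg reference error is a
  documented assumption about automatic oscillometric monitors, not a
  measured value.
- **Default subjects:** means 111.3 / 123.1 / 100.9 mmHg with within-subject
  sd 5.5 / 5.0 / 4.0 mmHg, so that 50-record calibration sets span roughly
  18–25 mmHg per subject and the pooled 150-record set spans about ±20 mmHg
  around 111.8 mmHg. Heart rates 68 / 74 / 61 bpm; the three subjects
  differ in bump geometry and pressure sensitivity so a pooled curve is a
  genuine compromise across individuals.
- **Seeding:** one master seed feeds named, disjoint `SeedSequence`
  sub-streams (per subject, per record, per noise source); the experiment is
  byte-identical across reruns with the same seed.

What the generator does *not* emulate: motion artifacts, sensor coupling
drift, respiratory modulation, arrhythmia, nonlinear or subject-specific
BP–morphology relationships beyond the linear slopes, and elderly waveform
patterns. Passing tests therefore demonstrate that the pipeline recovers
pressure when its structural assumptions hold, not that those assumptions
hold in any human population.

## Experiment design

Per subject, 50 calibration records build an individual curve evaluated on
that subject's 25 held-out validation records; a pooled curve is fit on all
150 calibration records and evaluated per subject and on the pooled 75
validation records. Validation is a genuinely separate record set — no
cross-validation at evaluation time. Under the default conditions the pooled
curve shows the expected contrast: a higher pooled-validation correlation
(the between-subject spread widens the pressure range) together with a
pooled SEP no better than the best individual curve. Because the pooled
correlation is range-inflated, SEP — not R — is the figure of merit to
compare across designs.

Default problem sizes (20 s records at 10 kHz, 75 records per subject,
L = 100, k_max = 10) run the full two-arm experiment in well under a minute
on one core; all sizes are configuration keys.

## Numerical choices and degenerate inputs

- Phase unwrapping forces successive differences into (−π, π]; isolated
  degenerate samples are interpolated, whole-record degeneracy raises.
- Gain estimation requires nonzero peak-to-peak swing on every channel.
- NIPALS declares rank exhaustion when the deflated covariance ‖X'y‖ or the
  score norm falls below a relative tolerance of 1e−12; requesting more
  factors raises rather than returning noise factors.
- PRESS folds whose training subset supports fewer factors carry the last
  supported model's prediction forward (its PRESS cannot improve further).
- F-ratio steps with PRESS(k+1) = 0 are treated as significant unless
  PRESS(k) is also 0 (exact-fit plateau → stop).
- Normalization maps min → 0 and peak → 1 exactly (affine map evaluated so
  the extremes are floating-point exact); a flat averaged beat raises.

## Known limitations

- The acceptance bounds on SEP and R hold under the synthetic conditions
  only; published human-subject accuracies are not reproducible from this
  package and are not targets.
- The F(n, n) degrees of freedom for the PRESS ratio are a pragmatic
  convention; other chemometrics software uses different dof or compares
  against the PRESS minimum, and selected factor counts may differ.
- The beat-period estimator assumes a quasi-stationary rhythm within each
  20 s record.
- `evaluate` assumes exchangeable validation records; no per-beat
  uncertainty is propagated into SEP.
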
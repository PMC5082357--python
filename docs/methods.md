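# Methods

## The kinematic filling model

Early diastolic transmitral flow is modelled as the recoil of a damped,
loaded spring. With the inertial mass fixed at m = 1 g (the convention of
the kinematic-filling literature, which makes the constants per-gram
quantities), the displacement obeys

    ẍ + c·ẋ + k·x = 0,    x(0) = x0,  ẋ(0) = 0,

and the measured quantity is the speed |ẋ(t)|. The three regimes have the
standard closed forms:

* underdamped (c² < 4k): v(t) = (k·x0/ω)·e^(−ct/2)·sin(ωt) with
  ω = √(k − c²/4), supported on [0, π/ω];
* critically damped: v(t) = k·x0·t·e^(−ct/2);
* overdamped: v(t) = (k·x0/β)·e^(−ct/2)·sinh(βt), β = √(c²/4 − k).

`model_velocity` clamps the underdamped branch to zero past π/ω (the wave
has ended) and classifies the regime by the discriminant c² − 4k with a
1e−9 relative tolerance; both neighbouring closed forms converge to the
critical one well outside that band, so the velocity is continuous across
the boundary (tested explicitly).

Parameter bounds are physical: k > 0, x0 > 0, c ≥ 0. Units follow the
clinical reporting convention: c g/s, k g/s², x0 cm, velocities cm/s,
forces converted dyn → mN (×0.01), energy erg → mJ (×10⁻⁴).

### Closed-form characteristics

* peak time: atan(2ω/c)/ω (underdamped; π/(2√k) at c = 0), 2/c (critical),
  artanh(2β/c)/β (overdamped); Vmax is the curve value there.
* duration: π/ω for oscillatory recoil. Critical/overdamped velocity never
  reaches zero, so the duration is defined as the decay of speed to a
  configurable fraction of Vmax (default 1 %); this keeps the VTI and the
  deceleration time Edec = duration − peak time finite.
* VTI: x0·(1 + e^(−cπ/2ω)) for the oscillatory case (total spring
  excursion), adaptive quadrature otherwise. KFEI = VTI/(2·x0)·100 % — the
  undamped reference wave with the same k, x0 has VTI = 2·x0 — which
  reduces to the x0-free closed form (1 + e^(−cπ/2ω))/2 · 100 %.

### tau

The package estimates the isovolumic pressure-decay constant from the
fitted constants by the quasi-static limit of the recoil equation: when
damping dominates inertia, c·ẋ + k·x ≈ 0 and the motion relaxes
exponentially with time constant c/k, reported in ms (tau = 1000·c/k). It
is positive, increases with impaired relaxation (larger c at fixed k), is
independent of load, and evaluates to 70–130 ms over the cohort-typical
constants. An undamped wave (c = 0) has no viscous relaxation to time, so
tau is returned as NaN rather than 0. This is an approximation index
derived from the E-wave only, not a replacement for invasive tau.

### Triad parameterization

Each damped-recoil wave is equally described by (AT, DT, Vmax): the
half-period fixes ω = π/(AT + DT), the peak condition fixes
c = 2ω/tan(ω·AT), then k = ω² + c²/4 and x0 follows from Vmax. AT = DT is
the symmetric undamped wave (c = 0); AT > DT would require negative damping
and is rejected. The inversion assumes the wave has a finite terminus
(oscillatory/critical regime) — a user-marked end point implies exactly
that. The round trip params → triad → params is exact to 1e−6 relative on
the underdamped domain (property-tested).

### Load-independent index

Across beats acquired at different loads, the peak driving force k·x0 is
regressed on the peak resistive force c·Vmax by unweighted ordinary least
squares; M is the slope (dimensionless), B the intercept (mN). Defined only
for ≥ 2 beats with non-identical resistive forces. No robust-regression
variant is offered because the index is defined as the plain slope.

## Envelope detection

A spectral-Doppler strip is a brightness image whose columns are time
(dt_per_col s/px) and rows velocity (dv_per_row (cm/s)/px) around a
baseline row. Column i carries the pixel-centre time (i + 0.5)·dt_per_col;
the flow onset set by the user (or by template matching) is a column
*boundary*, half a pixel before the first sample — getting this half-pixel
right matters, since onset misplacement propagates directly into the
constants.

Detection scans each column of the window top-down for the first pixel at
or above the threshold. The default threshold is derived from Otsu's split
of the window, but taken as the midpoint of the two class means: the
speckle tail reaches to the Otsu cut itself, and the midpoint clears it
with a wide margin on both sides. A candidate differing from the last
*accepted* velocity by more than max_jump (default 25 % of the strip's
velocity span — the original rule is only qualitative) is retained but
flagged rejected, so an isolated noise pixel cannot poison later columns;
the reference for the first sample is zero because flow starts from rest.

Two optional corrections shorten the deceleration limb toward clinical
practice (both on by default, individually switchable):

* zero-tail — the last two accepted velocities are set to zero (the wave
  must end at the baseline). Near-neutral on clean data.
* tangent shortening — after a first fit, the tangent to the fitted curve
  where velocity has fallen to 70 % of peak is extrapolated to the
  baseline; the resampled trace follows the curve to that point, the
  tangent to its intercept, zero beyond, and is then refit. Because the
  clinical deceleration line meets the baseline well before the model's
  exponential tail (0.32 s vs 0.40 s for the c = 17.3, k = 135 wave), this
  correction intentionally shortens the fitted Edec even on clean data; it
  is a harmonization with clinical practice, not a denoising no-op. On
  artifact-bearing strips it strictly reduces the Edec error (tested).

## Fitting

`PDFModel.fit()` minimizes the sum of squared velocity residuals over the
accepted samples with Levenberg–Marquardt. The physical bounds are enforced
by a smooth reparameterization — softplus for c, log for k and x0 — so the
unconstrained LM residual stays differentiable; a fit driven to c → 0
simply saturates the softplus. Initialization inverts the trace's empirical
triad (peak position, last accepted sample) through the closed form; when
the crude triad has AT > DT the start falls back to a symmetric wave with
the observed rise time and mild damping (c = 1 g/s). Standard errors are
Gauss–Newton (σ̂²·(JᵀJ)⁻¹) in the physical coordinates and NaN when the
Jacobian is degenerate (e.g. at the c = 0 boundary). No goodness-of-fit
gate is applied — the residual norm is recorded for diagnostics only, since
sum-of-squares differences do not separate physiologically better fits.

Noise-free traces sampled at 1 ms recover the constants to < 0.5 %; the
full pixel pipeline (render → DICOM → detect → fit) recovers them to < 2 %
(the residual error is the one-row velocity quantization), and to < 5 %
mean absolute error per constant under 3 cm/s Gaussian envelope noise
(50 replicates, seeded).

### Multi-beat loop

The first beat is fitted under user control and seeds the loop. For each
subsequent beat the onset is found by normalized cross-correlation against
an onset-centred template of the seed beat (match floor 0.6, configurable);
detection runs from the onset to 1/3 of a cardiac cycle or to where
velocity falls below 35 % of the wave's peak, whichever is earlier; and the
fitted c, k, x0 are compared with the mean over previously accepted beats
(seed included) — any relative deviation above 40 % discards the beat with
a recorded reason. The cycle length comes from heart-rate metadata when
present, else the median strip duration. Every beat lands exactly once in
the accepted or discarded list. The deviation test applies to the three
constants only, not to derived indices.

## DICOM and persistence

The reader locates the spectral-Doppler ultrasound region by its region
data type, crops the pixels to the region bounds and maps PhysicalDeltaX
(seconds), |PhysicalDeltaY| (cm/s) and ReferencePixelY0 (baseline row) into
the strip; the sign of PhysicalDeltaY orients the flow. Several spectral
regions: the largest area wins. Missing calibration raises an error naming
the attribute; a time calibration implying a sweep speed below 100 mm/s (at
an assumed 0.25 mm display pitch) warns but never fails, since low sweep
speed costs only temporal resolution. Multi-frame files yield one strip per
frame; long single strips are split into cycles using heart-rate metadata
or, as fallback, the autocorrelation of column intensity sums, with
boundaries aligned to the first flow onset. Folders mixing single-frame and
cine files are rejected outright.

Sessions are stored as versioned JSON (schema `ewavekit-session` v1)
holding strips, traces, settings and fits losslessly; this replaces the
original tool's proprietary workspace format so sessions stay portable and
testable. Anonymization strips case ids, provenance and source identifiers
at save or export time. Exports carry one row per beat plus mean/SD and
M/B, at full float precision; appending to a cumulative study database is
refused on any header mismatch.

## Reproducibility statistics

Cases are the units of analysis (per-patient means). CV is
100·SD(a−b)/mean(all values), reported as a magnitude so sign-negative
parameters (the damping index) stay comparable; SD uses n−1. The ICC
defaults to ICC(2,1) — two-way random effects, absolute agreement, single
measures — computed from the balanced two-way ANOVA mean squares (which are
returned with the value); ICC(3,1) is available where the raters are fixed.
The percentage difference is the absolute form, 100·|a−b|/pair mean, with
zero-mean pairs excluded loudly. The ICC implementation is cross-checked
against pingouin in the test suite.

## Synthetic data

The generator renders what the detection stage actually consumes: a filled
spectral band (bright from baseline to envelope, as PW spectra appear),
half-normal background speckle, optional Gaussian envelope jitter, optional
bright artifacts *above* the envelope during deceleration (the failure mode
the shortening corrections target), an optional late atrial wave, and
beat-to-beat parameter variation for load-ramp studies. Default geometry
emulates a 100 mm/s sweep at 0.25 mm pixel pitch (2.5 ms/column),
0.5 (cm/s)/row, a 160-row strip with the baseline at row 150, and a 0.8 s
cycle; the default constants (c 17.3 g/s, k 135 g/s², x0 11.4 cm) are a
published normal-range wave. Every generator is a pure function of its spec
and seed.

What the synthetic data does **not** emulate: transducer physics, spectral
broadening, wall filters, gain compression, respiratory motion, or genuine
E/A overlap morphology. Passing the recovery tests therefore demonstrates
the correctness of the algorithms on idealized spectra, not clinical
accuracy on patient images; cohort-level results from patient data are out
of scope here.

## Problem sizes and numerical choices

The test suite and acceptance script use one-cycle strips of 320 × 160 px,
50-replicate noise studies, 12-beat load ramps and 1000-draw oracle sweeps;
all complete in seconds. Tolerances: closed form vs oracle 1e−6 relative;
triad round trip 1e−6; LM termination at xtol = ftol = gtol = 1e−12 with at
most 2000 function evaluations. Ties and degenerate inputs fail loudly
(explicit error classes) rather than returning silent defaults.

## Known limitations

* tau is a package-derived quasi-static approximation, not a published
  regression against invasive measurements; treat it as an index.
* The triad inversion does not cover overdamped waves (by design: a marked
  terminus implies a zero crossing).
* Template matching assumes beat-to-beat shape similarity; a beat with very
  different rise dynamics can be located a few columns late and will then
  usually be rejected by the 40 % rule rather than silently accepted.
* The autocorrelation cine splitter needs at least ~1.3 cycles and clear
  periodicity; otherwise the strip is returned whole with a warning.
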
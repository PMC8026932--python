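# Methods

`qusrecur` implements a quantitative-ultrasound (QUS) radiomics pipeline for
pre-treatment recurrence-risk prediction from the radiofrequency (RF)
ultrasound signal of a metastatic cervical lymph node, together with a
synthetic RF generator that provides ground truth for every estimator.
This note records the models, the numerical choices, and what the synthetic
data can and cannot establish.

## Forward model (rf_simulator)

Each scan line is the axial convolution of a Gaussian-modulated pulse
(6.5 MHz center, −6 dB power points at the 3 and 8 MHz band edges) with a
random scatterer reflectivity, simulated in one 2-D imaging plane:

* **Diffuse component.** Scatterer count is Poisson with a density of 12
  per resolution cell (cell = axial resolution c/2B × line pitch);
  positions are uniform, amplitudes Rayleigh, scaled so that the incoherent
  backscattered power equals the acoustic concentration irrespective of the
  number density. Doubling the concentration therefore raises band power by
  exactly 3.01 dB.
* **Quasi-regular component.** When a mean spacing d > 0 is set, each line
  receives an axial train of fixed-amplitude scatterers whose gaps are
  d·(1 + jitter·ε), ε ~ N(0,1). The power spectrum of such a train ripples
  with period Δf = c/(2d) — the physical basis of the spacing estimator.
  The train amplitude is fixed at 4·√(concentration), which puts the ripple
  at roughly a third of the diffuse level within an analysis gate.
* **Scatterer size.** A Gaussian scattering envelope is applied exactly in
  the frequency domain so that the backscatter form factor is the
  Insana–Hall Gaussian exp(−0.827 k²a²) with a the effective radius.
* **Attenuation.** Frequency-linear amplitude loss 10^(−α·f·2z/20) applied
  with an overlap-add time-varying filter (triangular partition of unity
  over 128-sample depth bins). The piecewise amplitude crossfade deviates
  from the exact exponential by <0.1 dB mid-bin at band-edge frequencies.
* **Electronic noise.** Additive white Gaussian noise at −40 dB relative to
  mean signal power by default, switchable off.
* **No diffraction.** Beam formation is deliberately not modelled: tissue
  and phantom share one pulse, so the reference-phantom division cancels
  all system terms by construction. This is the minimal model that is
  honest for estimators whose whole premise is that normalization removes
  the system response.

The reference phantom is a dense (≥10 per cell) diffuse field of
zero-radius scatterers with no attenuation. `simulate_phantom` returns 16
independent frames (a probe sweep over the uniform phantom); reference
spectra are averaged over frames *and* the full lateral width. This
matters: a single phantom realization leaves frozen speckle noise in the
per-depth reference that propagates into every patient's spectra as a
shared depth-dependent error, biasing the attenuation estimate by up to
≈20 % at a 1.2 cm ROI. Frame averaging is also what the reference-phantom
method does in practice.

All randomness derives from one master seed through a counter-style
splitmix scheme (`derive_rng(seed, *indices)`), so patients, slices and
subset draws are independent yet exactly reproducible.

### Cohort defaults

The default cohort is 17 recurrence / 34 no-recurrence patients, 3 slices
each. Class tissue distributions overlap deliberately (recurrence: radius
30 ± 4 µm, concentration 1.6 ± 0.3, spacing 1.2 ± 0.1 mm, attenuation
0.60 ± 0.08; no-recurrence: 24 ± 4 µm, 1.0 ± 0.2, 1.0 ± 0.1 mm,
0.45 ± 0.08): recurrence prediction from nodal microstructure is a hard
problem and the default conditions are meant to be realistically hard, not
cleanly separable. Survival is exponential: the recurrence class draws
event times with a 9-month median hazard, truncated at the 64-month
follow-up horizon so labels and event flags agree; the no-recurrence class
draws censoring times with a 42-month median (the follow-up distribution),
capped at 64 months. Setting a class hazard to zero censors everyone at
the horizon.

## Spectral stage (spectral_features)

The ROI is tiled with ~2 mm × 2 mm windows (104 samples × 13 lines at the
default geometry) at 92 % overlap (step = max(1, 8 % of the window)). A
window is kept when it lies fully inside the slice and its **center** falls
in the ROI mask, which tolerates boundary windows without losing the rim of
small nodes. Per window, each line is Hann-tapered and zero-padded to the
next power of two ≥ 4× the window length; the line-averaged squared FFT
magnitude is divided by the phantom reference at the same depth, and
everything downstream sees only the 3–8 MHz band in dB.

* **MBF / SS / SI** — ordinary least squares line S(f) ≈ SS·f + SI (f in
  MHz); MBF = SS·fc + SI, so the identity holds to machine precision by
  construction.
* **ACE** — reference-phantom spectral-difference method: per band
  frequency, the row-mean normalized log-spectrum is regressed on window
  depth (dB/cm); the frequency slope of that decay rate, halved for
  two-way propagation, is the per-slice ACE. It needs ≥ 3 window rows.
* **Attenuation compensation** — once ACE is known, every window spectrum
  is compensated by +2·ACE·f·z dB before the remaining estimators run.
  Without this the depth tilt contributes roughly five times the
  form-factor signal to the ASD regression; with it, per-window estimates
  inherit only the ACE estimation error.
* **ASD / AAC** — Gaussian form-factor inversion: ln P_norm is regressed on
  k², the slope giving a = √(max(0, −slope)/0.827) and ASD = 2a, the
  intercept giving AAC in dB. The phantom's own Rayleigh (f⁴) frequency
  dependence cancels in the normalization, so no explicit f⁴ term appears.
  AAC is self-calibrated: the phantom's known concentration is pinned to
  95 dB (mid gray-scale), making tissue AAC a relative quantity — absolute
  calibration is unrecoverable and unnecessary for radiomics.
  ASD is clipped to [1, 200] µm and flagged when clipped or when the slope
  is non-physical (positive).
* **SAS** — the spacing ripple is sought in the normalized spectral
  autocorrelation. Two resolution facts drive the design. First, a 2 mm
  gate has ≈0.6 MHz spectral resolution (Hann), which cannot resolve the
  ripple of spacings ≳1.3 mm, while the admissible range extends to
  2.5 mm; SAS therefore uses a dedicated 5 mm axial gate (2× the window
  laterally) centred on each window. Second, one gate holds only a few
  spacing periods, so a single autocorrelation is speckle-dominated;
  per-window SAS averages the autocorrelations over a ±2.5 mm lattice
  neighbourhood before peak-picking (ripple lag is shared by neighbours,
  speckle is not). Spectra are detrended (line fit removed) first so the
  backscatter slope cannot mask the periodicity. The peak chosen is the
  **most prominent** local maximum (height ≥ 0.1 after normalization) in
  the lag range mapping to [0.2, 2.5] mm, refined parabolically;
  m-th-neighbour separations produce peaks at sub-multiple lags, so a
  first-peak rule would systematically return twice the true spacing.
  Windows without an admissible peak fall back to 2.5 mm, flagged.
* **Slice aggregates** — besides the per-window maps, each slice reports
  low-noise ROI-aggregate estimates used for parameter-recovery checks:
  MBF/SS/SI from the window-averaged compensated spectrum; ASD/AAC from a
  joint fit of ln P = b + s·k² − q·f·z over all (window, frequency)
  samples, which estimates the attenuation tilt simultaneously instead of
  inheriting the ACE error (variance inflation ≈2 from the partial
  collinearity of k² and f·z, against a ~5× bias without it); SAS from the
  window-averaged autocorrelation. Spacing jitter keeps the ripple
  coherent within a gate but not across the ensemble-averaged spectrum,
  which is why autocorrelations, not spectra, are averaged.

Per-window estimates are intentionally noisy — a 2 mm gate carries ~6
independent spectral samples, so window ASD scatters widely and ~10 % of
windows flag a non-physical slope even when the true radius is 25 µm. The
parametric maps inherit that speckle statistics, as real QUS maps do; the
patient-level features average it down.

## Texture stage

The six mapped parameters (not ACE, which is a per-slice scalar) are
quantized onto fixed, cross-patient gray scales — MBF [−10, 25] dB,
SS [−8, 22] dB/MHz, SI [−10, 60] dB, AAC [20, 170] dB, ASD [1, 200] µm,
SAS [0.2, 2.5] mm — into 16 uniform levels. Fixed ranges are what makes
texture comparable across patients; 16 levels balances gray-scale
resolution against sparse co-occurrence matrices for ROIs near the 1 cm
minimum. For each map, a symmetric GLCM is accumulated over pairs whose
*both* cells are defined, for distances 1–4 and angles 0/45/90/135°;
energy, contrast, homogeneity and correlation are computed per offset and
averaged over the 16 offsets (feature averaging keeps each offset
inspectable; matrix averaging would not). A constant map has zero marginal
variance, making correlation 0/0; it is defined as 1 (a constant map is
perfectly predictable) and flagged. 6 maps × 4 statistics = 24 texture
features; with the 7 primaries, 31 per patient.

Cross-slice aggregation is the area-weighted mean (weights = in-ROI window
counts) for both primaries (window-mean per slice first) and textures.

## Cohort statistics and the classifier engine

Features are Z-scored with sample (n−1) statistics; in cross-validation the
statistics come from the training rows only and are reapplied to the
held-out row. Univariate comparisons run Shapiro–Wilk per group at
α = 0.05; only if both groups pass is a Welch t-test used (17 vs 34 makes
pooled variance unsafe), otherwise a two-sided Mann–Whitney U (exact when
the combined n ≤ 20 and tie-free).

The classifier engine evaluates three families — Fisher's linear
discriminant (closed form, ridge 1e-6 when the pooled scatter is
singular), k-nearest neighbours (k ∈ 1..5; distance ties break to the
lower training index, even-k vote ties to recurrence, the clinically
costly miss), and an RBF SVM (C, γ ∈ 2⁰..2¹⁰, the 11×11 = 121-pair grid) —
under leave-one-out cross-validation with a class-balancing ensemble:

1. Per fold, seven subsets keep every minority-class training patient and
   draw an equal number of majority-class patients without replacement
   (independent draws across subsets, seeded per fold).
2. Per subset, sequential forward selection grows a feature set (≤ 3,
   matching the n/10 rule for the 34-patient majority group) greedily by
   inner-LOO **balanced** accuracy, stopping when no addition strictly
   improves it; ties go to the lower canonical column index.
3. Hyperparameters (KNN's k, the SVM grid) are then selected on the chosen
   feature set by the same inner-LOO criterion (ties to the smaller value),
   and the subset model is fitted. Running the full grid inside every SFS
   candidate evaluation would cost O(10⁸) fits per cohort; the two-stage
   order (selection with mid-grid defaults, then tuning) is the standard
   wrapper arrangement. Balanced accuracy guards the small downsampled
   subsets against majority drift.
4. The held-out patient gets seven votes; ≥ 4 declares predicted
   recurrence. The vote fraction (0/7..7/7) is the ensemble score used for
   the rank-based ROC/AUC (midranks for ties); FLD/SVM additionally expose
   the mean decision value.

The ensemble is nested *inside* the outer fold — the only arrangement in
which neither normalization statistics, nor subset draws, nor feature
selection can see the held-out patient. A perturbation test asserts this:
changing the held-out patient's features changes nothing in that fold's
trained models. Fold and subset seeds derive from (config seed, fold index,
subset index) only. Inner-LOO SVM evaluations go through scikit-learn's
low-level libsvm binding (≈20× less call overhead than the estimator API;
a test pins exact agreement with `SVC`), with a transparent fallback to the
public estimator.

`synthetic_feature_table` provides the feature-level validation cohort: 31
columns of bounded uniform within-class noise with a class gap of 5
within-class standard deviations on four informative columns (ASD, SAS,
ASD-CON, SAS-CON) and pure noise elsewhere. Bounded noise means the gap is
a true margin — the engine is validated under conditions where near-perfect
LOO performance is actually attainable, which Gaussian tails at the same
nominal separation do not guarantee with single-feature subset models.

## Survival stage

Recurrence-free survival uses the Kaplan–Meier product-limit estimator
(lifelines behind the module surface), with censored subjects remaining at
risk at their own time and events counted before censorings at tied times.
Greenwood 95 % intervals are stored. Groups defined by the *predicted*
label are compared with the one-degree-of-freedom log-rank test, and
milestone RFS is read off the step functions at 24/36/60 months; queries
beyond the last observed time carry the last value and warn.

## What the synthetic data does not show

The generator validates the machinery, not the clinic. It emulates
speckle, quasi-regular scatterer spacing, size/concentration contrasts and
attenuation, but not beam diffraction, phase aberration, intra-nodal
heterogeneity (each synthetic node is homogeneous, so texture features
mostly reflect estimation speckle rather than biology), operator-dependent
ROI placement, or any true biological coupling between microstructure and
recurrence hazard — class differences are injected by construction.
Passing tests therefore demonstrate that the estimators recover known
ground truth and that the evaluation protocol is leakage-free and
calibrated (label-permuted AUC ≈ 0.5); they do not demonstrate clinical
predictive power, which requires the patient data the pipeline was built
to analyse.

## Problem sizes

Default slices are 1216 samples × 160 lines (≈2.3 × 2.4 cm) with a
12 × 14 mm elliptical ROI (≈5,700 windows/slice), three slices per
patient. The classifier validation cohort is 8 + 16 patients; the
end-to-end acceptance run uses the full 17 + 34 default cohort. These
sizes keep a complete test-suite-plus-acceptance cycle in the
ten-minute range on one CPU while leaving every code path (including the
121-point SVM grid inside 7-subset, n-fold nested LOO) fully exercised.
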
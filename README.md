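# qusrecur

Quantitative-ultrasound (QUS) radiomics for predicting disease recurrence in
node-positive head-and-neck squamous cell carcinoma treated with radical
radiotherapy.

Before treatment, the most prominent metastatic cervical lymph node is
scanned with a clinical linear probe (6.5 MHz center, 3–8 MHz band, 40 MHz
sampling) and the raw radiofrequency (RF) echo signal is retained. Because
RF keeps the spectral content that B-mode imaging discards, calibrated
spectra probe the tissue microstructure: scatterer size, concentration,
spacing and attenuation. This package implements the full analysis chain
that turns one such exam into a recurrence-risk prediction — and, since the
patient data are not public, a physics-based RF simulator that provides
known ground truth for every stage.

The pipeline:

1. **Spectral features** — the node ROI (3–5 slices) is tiled with
   2 mm × 2 mm windows at 92 % overlap; each window's power spectrum is
   normalized by a tissue-mimicking reference phantom, cancelling the
   system response. Per window, seven QUS parameters are estimated:
   mid-band fit (MBF), spectral slope (SS), 0-MHz intercept (SI) from the
   Lizzi–Feleppa line fit; average scatterer diameter (ASD) and acoustic
   concentration (AAC) from Gaussian form-factor inversion
   (ln P ∝ −0.827 k²a²); spacing among scatterers (SAS = c/2Δf from the
   spectral-autocorrelation ripple); and the attenuation coefficient
   estimate (ACE, dB·cm⁻¹·MHz⁻¹) by the spectral-difference method.
2. **Texture** — the six parametric maps (all but ACE) are quantized onto
   fixed gray scales and summarized with grey-level co-occurrence (GLCM)
   energy, contrast, homogeneity and correlation, averaged over distances
   1–4 and angles 0/45/90/135°, then area-weighted across slices:
   7 + 24 = 31 features per patient.
3. **Classification** — Fisher's linear discriminant, k-nearest neighbours
   (k ∈ 1..5) and an RBF SVM (C, γ ∈ 2⁰..2¹⁰) with sequential forward
   selection (≤ 3 features), evaluated by leave-one-out cross-validation.
   Class imbalance is handled by an ensemble of seven balanced subsets
   (majority class downsampled) whose majority vote labels the held-out
   patient; every statistic is recomputed inside each fold, so nothing
   leaks.
4. **Survival** — Kaplan–Meier recurrence-free survival by *predicted*
   group, compared with the log-rank test.

## Worked example

Estimate the seven spectral parameters from one simulated slice whose
ground truth is known (`examples/02_spectral_parameters.py`):

```
$ python examples/02_spectral_parameters.py
5722 windows analysed
window means:
  MBF     3.482
  SS     -0.379
  SI      5.943
  AAC    99.965
  ASD    45.065
  SAS     0.997
ROI-aggregate estimates vs truth:
  ASD   43.8 um   (truth 50.0)
  SAS  1.005 mm   (truth 1.000)
  ACE  0.484 dB/cm/MHz (truth 0.500)
flagged: {'ASD_clipped': 282, 'SAS_fallback': 0, 'SAS_aggregate_fallback': 0}
```

The tissue was simulated with 25 µm effective scatterer radius (ASD
truth 50 µm), 1.0 mm quasi-regular spacing and 0.5 dB/cm/MHz attenuation;
the estimators recover all three from the normalized spectra (single-slice
ASD scatters a few µm around truth; averaging an exam's 3 slices tightens
it). MBF/SS/SI describe the normalized spectrum's line fit in dB — near
flat here, as the Gaussian form factor is the only spectral shaping left
after phantom division and attenuation compensation.

Run the classifier engine on a well-separated synthetic cohort
(`examples/05_classification.py`):

```
$ python examples/05_classification.py
n = 24 patients, family = knn
confusion: TP 8  FN 0  TN 16  FP 0
sensitivity 100.0 %  specificity 100.0 %  accuracy 100.0 %  AUC 1.000
most selected features (subset x fold counts):
  ASD      167
  SAS      1
```

With a true inter-class margin the nested ensemble is perfect and the
forward selection almost always picks the informative ASD column first —
the engine finds exactly the features that were made informative.

Other scripts in `examples/` cover simulation, texture, the univariate
report and the survival comparison. The end-to-end pipeline is also
available as a CLI:

```bash
qus-recur run-all --demo --out demo_run --seed 3   # 12-patient cohort, ~1 min
```

which writes `features.csv`, `univariate.csv`, `classify_knn.json`,
`roc_knn.csv`, `km_curves.csv`, `survival.json` and a `provenance.json`
whose outputs are byte-identical on reruns of the same config.

## Layout

```
src/qusrecur/
  simulate.py   # RF forward model, phantom, labelled cohorts
  spectra.py    # windows, phantom normalization, 7 QUS estimators
  texture.py    # quantization + GLCM statistics + slice aggregation
  features.py   # 31-feature table, Z-scoring, univariate tests
  classify.py   # FLD/KNN/SVM, SFS, balanced ensembles, LOO protocol
  survival.py   # Kaplan-Meier + log-rank by predicted group
  io.py         # HDF5 exam containers, manifests, feature tables
  cli.py        # qus-recur subcommands and run configuration
docs/methods.md # models, assumptions, numerical choices, limitations
```
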
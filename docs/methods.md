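# Methods

This note documents the models, conventions and numerical choices behind
`pdqeeg`, and what the synthetic-data experiments do and do not demonstrate.

## Synthetic EEG

A recording is modelled as a linear mixture of band-limited cortical
sources. For each of the five bands, `k_sources = 2` shared source signals
are synthesised by random-phase Fourier synthesis with spectrum strictly
confined to the band (so band variances are analytic, with no filter-skirt
leakage), mixed into channels with random weights, plus a small per-channel
noise term (`noise_frac = 0.05` of variance) carrying the same band
profile. Mixture weights are normalised so that every channel's variance
splits across bands exactly in the requested proportions; the per-channel
RMS is scaled to 40 µV.

The low-rank mixture is deliberate: scalp EEG is a volume-conducted
superposition of a limited number of cortical generators, and this is the
generative model that ICA-based artifact removal assumes. With 24 channels
(default montage, plus a flat Cz reference at the vertex) and 11 sources the
decomposition is overdetermined, which is what makes fully automated blink
removal reliable; a square or underdetermined configuration degrades the
separation measurably.

Blinks are 300 ms raised-cosine transients at 8× the median channel SD,
confined to the designated frontal channels (the first 10% of the montage).
Bad channels are either flat or scaled ×10. Background, blink and
bad-channel randomness come from independent streams of the same seed, so
the artifact-free "twin" of a recording is bit-identical outside the
artifacts — the basis of the artifact-removal accuracy tests.

Default duration is 180 s (no canonical value exists for this design;
configurable). Tests and the acceptance script use 60–90 s recordings,
which are long enough for the spectral estimates they check.

What the generator does *not* emulate: spatial alpha gradients, spindles,
asymmetries, muscle/ECG artifacts, non-stationarity, or item-level
cognitive responses. Passing tests therefore demonstrate correctness of the
estimators and the inference chain under a controlled source-mixture model,
not clinical validity on real recordings.

## Preprocessing

* **Filtering.** Least-squares FIR designs (band-pass order 2500, notch
  order 1000), applied forward–backward for zero phase so group delay
  cannot bias band power. The compound response is flat within ±0.5 dB over
  1–30 Hz with ≥ 40 dB attenuation below 0.25 Hz and at 50 Hz (verified by
  direct frequency-response evaluation at 200 and 1000 Hz sampling).
* **Bad channels.** A channel is flagged when its robust variance (squared
  MAD) is below 10⁻³× or above 9× the cross-channel median, or when its
  best absolute correlation with any other scalp channel is < 0.1.
  Deterministic; thresholds are arguments.
* **Spherical-spline interpolation.** Classic scalp-spline interpolation
  (stiffness m = 4, ridge 10⁻⁵, 50 Legendre terms), written as a single
  interpolation operator; it reproduces constant fields exactly and is
  cross-checked against MNE's implementation in the tests. Interpolation
  runs *before* ICA so the decomposition never sees flat or runaway
  channels.
* **ICA blink removal.** FastICA on the scalp channels with the component
  count set to the numerical rank of the data (interpolated channels are
  exact linear combinations and would otherwise poison the whitening).
  Components are removed when activation kurtosis exceeds 5 (blink trains
  are sparse and heavy-tailed) or when > 60% of mixing-column energy loads
  on the frontal channels. Fixed seed ⇒ identical output; a failed
  decomposition passes the recording through with a logged warning.

## Spectral biomarkers

Multitaper PSD with DPSS tapers on 8 s epochs, 50% overlap,
eigenvalue-weighted, averaged over epochs. The smoothing parameter
`half_bandwidth = 0.5 Hz` gives a time–(half)bandwidth product NW = 2 and
3 tapers, i.e. a ±0.25 Hz smoothing kernel. This matters: alpha1 is only
2 Hz wide, and a ±0.5 Hz kernel (4 s epochs at the same taper count)
systematically smears ~25% of a narrow band's mass into its neighbours and
delta mass below the 1 Hz integration edge — a bias of up to 0.04 in the
relative power of plausible spectra, which no amount of recording length
removes. With the defaults the generator→estimator round trip is accurate
to ≤ 0.024 absolute across all bands and seeds tested. Epoch length,
bandwidth and overlap are all configurable.

Conventions:

* GRMP takes the **median across scalp channels first**, then normalises
  ("global median spectrum"); the per-channel-relative alternative is a flag.
* Band edges are half-open `[low, high)`; 10 Hz belongs to alpha2.
* The relative-power denominator is 1–30 Hz (the union of the five bands),
  so the five fractions sum to exactly 1; 0.5–70 Hz is available by
  configuration.
* The occipital median frequency is a type-1 weighted quantile of the
  4–14 Hz occipital median spectrum: the first grid frequency at which the
  cumulative power reaches half the total. A point mass at f returns f
  exactly; for continuous spectra the result is within one frequency bin of
  the continuous median.

## Cognitive scoring and outcome

z = ±(raw − norm mean)/norm SD per test, with the sign flipped for
lower-is-better measures (times, errors, omissions, time ratios of the
executive domain) so every aggregate is higher-is-better. Domain scores are
unweighted means of member-test z-scores (3/3/2/2/2/2 tests across
attention, executive, fluency, long-term memory, working memory,
visuospatial); the OCS is the mean of all 14 z-scores, *not* the mean of
the six domain means. Subjects with any missing test are dropped and
logged. Mood scales (BDI-II, PDQ-39 emotional well-being, OCI) are carried
as covariates only.

CI-OCS divides the paired OCS change by the cohort SD of the paired
differences — computable from the data alone, with no external reliability
coefficient. The Jacobson–Truax variant (√2·SEM from a supplied test–retest
r) is available as an option. The index is exactly antisymmetric under
visit swap and invariant to adding a constant to both visits.

## Planted cohort model

The generator plants

    t_i = intercept + β_θ·GRMPθ_i + β_exec·Exec_i + β_wm·WM_i + ε_i

and shifts every follow-up test z-score by t_i, so the paired OCS
difference equals t_i exactly. Because the observed CI-OCS divides by the
cohort SD of those differences, the estimable coefficients are β/SD(t). The
default `noise_sd = 0.84` is chosen so that Var(t) ≈ 1 under the default
coefficients (−3.16, 0.54, 0.19) and covariate scales — then the planted
coefficients are recovered on their own scale. Users who change betas or
feature spreads should expect a corresponding uniform rescaling.

Band fractions are sampled logistic-normally around the cohort-typical
medians (log-scale spread 0.35); domain latents are N(−0.1, 0.9); clinical
covariates follow truncated normal/log-normal laws matching published
baseline ranges (age 67 [31, 84], LEDD median ≈ 690 mg [150, 2129],
UPDRS-III ≈ 14, education 14 y [9, 20], …). Follow-up MMSE is linked to the
planted change index (27.5 + 2·CI plus noise, clipped to [0, 30]) so the
MMSE < 24 dichotomy used by the ROC stage occurs at a realistic rate.

## Statistical chain

* **Screen.** One OLS per predictor; selected when p ≤ α = 0.05. No
  multiplicity correction by default (Benjamini–Hochberg available).
* **Backward elimination.** Iteratively removes the predictor with the
  largest partial-t p-value until all are ≤ α. Exact p ties are broken by
  removing the alphabetically later name, making the result independent of
  column order. Condition numbers > 10¹⁰ raise an error naming the columns.
* **LMG.** Exact enumeration over all predictor subsets with combinatorial
  weights (≤ 12 predictors; the models here have ≤ 6 candidates). Shares
  are reported on the outcome-variance percentage scale and sum to the
  model R²·100 — non-normalised by design, so the total is the model's
  explained variance, not 100%. The implementation is verified to 10⁻¹⁰
  against a brute-force average over all orderings.
* **Confounding.** For each key predictor: R² of the predictor-only model
  versus the predictor's LMG share in the predictor + {age, sex, education}
  model; "no confounding" when the change is < 20% of the unadjusted share
  (reporting threshold, configurable).
* **ROC.** Empirical curve over all thresholds, trapezoidal AUC, operating
  point at maximal Youden's J with ties resolved toward higher specificity.
* **Random forest.** 500-tree regression forest (mtry = p/3). MDA is the
  per-tree out-of-bag MSE increase under single-column permutation,
  averaged over trees; MDGC is the node-variance decrease summed over
  splits and trees — variance reduction is the regression analogue of Gini
  impurity, which is undefined for continuous outcomes. Both are
  seed-deterministic.

## Known behaviour of screen + elimination with many candidates

With ~19 candidate predictors of which 16 are conditionally null, the
univariate screen at α = 0.05 followed by backward elimination at the same
α retains at least one false predictor in roughly a quarter to a third of
cohorts at n = 500: each null passes the screen with probability ≈ 0.05
*and is then selected for significance*, so it survives elimination far
more often than an unscreened null would. The probability that the final
model is *exactly* the planted triple is therefore structurally capped
around 0.7–0.8 — a property of the selection procedure itself, not of the
implementation. The pipeline reports three recovery rates separately
(exact-set, contains-all, exact-set with all CIs covering truth); the
contains-all rate exceeds 90% and per-coefficient CI coverage is at the
nominal 95%.

## Determinism

Every stochastic component (generators, ICA, forest) takes an explicit
seed; the pipeline derives per-stage and per-subject seeds from one master
seed via `numpy.random.SeedSequence`. Re-running an identical config
reproduces every output file bit-exactly.

## Limitations

* The normative table is synthetic (plausible instrument means/SDs), not a
  real normative database.
* A reduced labelled montage stands in for high-density geodesic nets; no
  electrode-coordinate database is shipped.
* The ICA stage targets blinks only; muscle/ECG artifacts are out of scope.
* LMG is exact-enumeration only (≤ 12 predictors); no sampling mode.
* No mixed-effects or survival extensions, and no external validation
  machinery.
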
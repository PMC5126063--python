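# pdqeeg

Quantitative-EEG biomarkers and prognostic models for cognitive decline in
Parkinson's disease (PD).

Resting-state EEG slows as PD-related cognitive impairment develops: power
shifts from the alpha/beta range into theta and delta. This package
implements, as a tested and reusable pipeline, the analysis chain used in
prospective qEEG cohort studies of PD:

1. **Automated EEG preprocessing** — zero-phase least-squares FIR band-pass
   (0.5–70 Hz) with a 50 Hz notch, robust bad-channel detection with
   spherical-spline interpolation, and ICA-based removal of eye-blink
   components. No operator interaction anywhere.
2. **Spectral biomarkers** — multitaper power spectral density (DPSS tapers),
   collapsed to the **global relative median power** (GRMP): the
   channel-median spectrum, integrated over delta (1–4 Hz), theta (4–8 Hz),
   alpha1 (8–10 Hz), alpha2 (10–13 Hz) and beta (13–30 Hz) and normalised so
   the five fractions sum to one; plus the **occipital median frequency**,
   the 50% quantile of the 4–14 Hz occipital spectrum.
3. **Cognitive outcome** — 14 neuropsychological tests are z-scored against
   a normative table (lower-is-better scores sign-flipped), averaged into
   six domain scores and an overall cognitive score (OCS, mean of all 14
   z-scores). The follow-up outcome is the change index

   CI-OCS = (OCS_followup − OCS_baseline) / SE_diff,

   a reliable-change-type statistic with SE_diff the cohort SD of the paired
   differences.
4. **Prognostic models** — univariate OLS screen (α = 0.05) → multivariate
   backward elimination → LMG relative-importance decomposition of the
   explained variance (non-normalised: shares sum to the model R², not
   100%) → confounder checks (age, sex, education) → ROC analysis of the
   MMSE < 24 follow-up dichotomy → random-forest importances (out-of-bag
   permutation MDA and node-impurity MDGC).

Because the clinical cohorts behind such studies are not public, the package
ships a first-class **synthetic-data generator**: EEG with exactly
controlled band-power fractions, blink artifacts and bad channels, and
two-visit cognitive tables whose CI-OCS is a planted linear function of
baseline GRMP theta, executive function and working memory — so every stage
has a recoverable ground truth.

## Worked example

Run a complete synthetic study (50 subjects, feature-level EEG sampling)
from the shell:

```sh
pdqeeg run-all --seed 5 --n-subjects 50 --outdir demo_run
```

which prints:

```
Final multivariate model
  executive                beta= 0.525  p=0.00017
  grmp_theta               beta=-4.276  p=0.034
  adjusted R2 = 0.306  (n = 50)
Explained variance (LMG, non-normalised) = 33.5%
  executive                 25.2%
  grmp_theta                 8.3%
ROC: AUC=0.73 sens=0.67 spec=0.90
Random forest: top predictor executive (MDA=0.165, MDGC=82.6)
```

The cohort was generated with planted coefficients −3.16 (GRMP theta), 0.54
(executive) and 0.19 (working memory). At n = 50 the screen recovers the two
strongest predictors — the theta coefficient −4.28 carries a wide confidence
interval that covers the planted −3.16 — and the LMG decomposition
attributes most of the explained outcome variance to executive function.
`demo_run/` contains the features and scores tables (TSV), the full model
report (JSON + text), the LMG bar chart and the ROC curve.

The same run with `--eeg-mode simulate` synthesises, preprocesses and
spectrally analyses one multichannel EEG recording per subject instead of
sampling features directly (slower; used to validate the EEG path).

Library use mirrors the CLI:

```python
import pdqeeg as pq

rec = pq.generate_eeg(pq.EEGGenSpec(duration=180.0, blink_rate=6.0, seed=1))
clean = pq.preprocess_recording(rec, seed=1)
sf = pq.compute_spectral_features(clean)   # sf.grmp["theta"], sf.occipital_mf
```

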
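# ctibm — CT imaging-biomarker survival signatures

`ctibm` is a tested, reusable implementation of the imaging-biomarker
(IBM) workflow used to predict survival of oesophageal squamous cell
carcinoma patients after definitive chemoradiotherapy from their
pre-treatment contrast-enhanced planning CT. It is aimed at
radiation-oncology and radiomics researchers who want the full chain —
feature extraction through decision-curve analysis — as composable,
auditable Python rather than one-off scripts.

The chain:

1. **3D feature extraction.** For a scalar volume with an aligned binary
   tumour mask (NIfTI, native anisotropic spacing), exactly 96 features:
   24 first-order intensity statistics, 20 geometric descriptors and 52
   texture features from the four grey-level matrix families (GLCM 20,
   GLRLM 16, NGTDM 5, GLSZM 11) on a 32-level discretisation.
2. **Pre-selection.** Univariable Cox screen (keep Wald p < 0.25), then
   pruning of correlated pairs (|r| ≥ 0.8, higher univariable p leaves),
   then variance inflation factors as a collinearity diagnostic.
3. **The IBM score.** An L1-penalised Cox model over the retained
   features; the penalty λ is chosen at the minimum of 10-fold
   cross-validated partial-likelihood deviance. The score of a patient
   is the model's log-partial hazard plus the smallest multiple of 0.1
   that makes all training scores positive:

   score(x) = Σₖ βₖ · x̃ₖ + c,  x̃ₖ standardised features.

   The two published formulas — overall survival (11 terms, c = +2.5)
   and progression-free survival (8 terms, c = −1.4) — ship as frozen
   scorers (`published_formula("OS"/"PFS")`).
4. **Evaluation.** Harrell's C-index with bootstrap CIs; time-dependent
   ROC (cumulative cases / dynamic controls, Kaplan-Meier censoring
   weights); Youden-index cutoff learned on training and applied frozen
   to validation; Kaplan-Meier curves, log-rank tests and hazard ratios
   for the resulting high/low-risk groups; multivariable Cox with
   optional backward likelihood-ratio elimination; cohort balance
   tests (t-test / chi-squared).
5. **Nomogram and decision curves.** Individual survival prediction
   S(t|score) from a univariable Cox model with a Breslow baseline, and
   net-benefit curves against treat-all/treat-none with event
   probabilities estimated by Kaplan-Meier within the treated group.

Because the original 154-patient imaging data are not public, the
package ships a first-class synthetic-cohort generator: ellipsoidal
tumours on anisotropic CT-like grids with a tunable correlated texture,
and exponential survival whose hazard is tied to generative parameters
so that specific features are informative by construction. Every stage
is testable end-to-end without external data.

## Worked example

```python
import numpy as np
from ctibm.synthetic import TumourParams, generate_tumour
from ctibm.features import extract_all
from ctibm.pipeline import PipelineConfig, run_pipeline

vol, roi, _ = generate_tumour(TumourParams(), seed=7)
feats = extract_all(vol, roi)
print(f"extracted {len(feats)} features; "
      f"Volume = {feats['Volume']:.0f} mm3, Sphericity = {feats['Sphericity']:.3f}, "
      f"Coarseness_NGTDM = {feats['Coarseness_NGTDM']:.4f}")

report = run_pipeline(PipelineConfig(seed_simulation=1, bootstrap_reps=200))
val = report["evaluation"]["validation"]
print(f"retained features: {len(report['preselection']['retained_after_pruning'])}")
print(f"lambda* = {report['signature']['chosen_lambda']:.4f}, "
      f"{report['signature']['n_nonzero']} nonzero terms, "
      f"constant = {report['signature']['formula']['constant']}")
print(f"validation C-index = {val['c_index']:.3f} "
      f"(95% CI {val['c_index_ci'][0]:.3f}-{val['c_index_ci'][1]:.3f})")
print(f"high-vs-low HR = {val['hazard_ratio']:.2f}, log-rank p = {val['logrank_p']:.2g}")
```

Output:

```
extracted 96 features; Volume = 7611 mm3, Sphericity = 0.647, Coarseness_NGTDM = 0.0029
retained features: 13
lambda* = 0.0684, 8 nonzero terms, constant = 1.6
validation C-index = 0.681 (95% CI 0.589-0.787)
high-vs-low HR = 3.82, log-rank p = 0.00011
```

Reading it: the simulated 154-patient cohort (99 training / 55
validation) carries a planted size + texture effect. Pre-selection
keeps 13 of 96 features; cross-validation picks λ ≈ 0.068, leaving 8
features in the score, whose training minimum fixes the constant at
1.6. On the held-out 55 patients the score ranks survival with C = 0.68,
and splitting at the training-derived Youden cutoff separates risk
groups with a hazard ratio of 3.8 (log-rank p ≈ 1e-4). Applying the
frozen published scorer instead is one call:
`ibm_score(features, published_formula("OS"))`.

The same steps are available from a shell via the `ibm` command
(`ibm extract`, `ibm preselect`, `ibm fit`, `ibm score`, `ibm evaluate`,
`ibm dca`, `ibm run`).

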
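# plcscore

Radiologic pattern scoring and diagnostic-accuracy analysis for predicting
neoplastic invasion of the **posterior laryngeal compartment (PLC)** and
**cricoarytenoid unit (CAU)** in cT3 glottic squamous cell carcinoma with
arytenoid fixation.

Arytenoid fixation classifies a glottic tumor as cT3, but the fixation may
be caused by true neoplastic infiltration of the CAU or merely by edema,
inflammation, or mass effect — conditions with very different treatment
implications. High-resolution MR with surface coils lets a radiologist code
each of seven PLC subsites (posterior vocal muscle, posterior and inferior
paraglottic space, arytenoid, cricoid lamina, lateral cricoarytenoid and
cricothyroid muscles) with one of three signal patterns:

- **A** — normal signal (score 0),
- **B** — T2 hyperintensity without diffusion restriction, i.e.
  edema/inflammation (score 1),
- **C** — intermediate T2 signal with diffusion restriction, i.e.
  tumor-like tissue (score 2).

`plcscore` takes those per-subsite codes (human input — no image
processing happens here) plus a binary histological reference standard and
computes, per patient,

- **Overall Score** = Σ subsite scores ∈ [0, 14],
- **Partial Score B** = number of Pattern-B subsites ∈ [0, 7],
- **Partial Score C** = 2 × number of Pattern-C subsites ∈ [0, 14],

and, per cohort, the full diagnostic-accuracy analysis: tie-corrected
Spearman ρ of each composite against histology (Fisher-z 95% CI,
t-approximation p-value), the empirical ROC curve of Partial Score C with
AUROC via the Mann–Whitney identity
(AUROC = P(S₊ > S₋) + ½P(S₊ = S₋)), DeLong / Hanley–McNeil / bootstrap
confidence intervals, the Youden-optimal cutoff (J = sens + spec − 1, rule
"positive if score ≥ cutoff"), and a pattern-prevalence summary. A
synthetic-cohort simulator with an exact analytic AUROC oracle supports
method validation at any sample size.

The 17-patient reference cohort on which the published statistics rest is
shipped as a packaged fixture (`load_table2_fixture()`).

## Worked example

```python
from plcscore import load_table2_fixture, run_full_analysis
from plcscore.report import render_text

report = run_full_analysis(load_table2_fixture())
print(render_text(report))
```

prints

```
Spearman correlation with histology (rho [95% CI], p):
  Overall Score    +0.6898 [+0.313, +0.879], p=0.0022
  Partial Score B  -0.0124 [-0.490, +0.471], p=0.9624
  Partial Score C  +0.7789 [+0.477, +0.916], p=0.0002

AUROC (Partial Score C): 0.931 [0.816, 1.000] (delong)

Youden-optimal cutoff: score >= 2
  sensitivity 100%  specificity 78%  J=0.778
  confusion: TP=8 FP=2 TN=7 FN=0
```

Read: the Pattern-B composite carries no diagnostic signal (ρ ≈ 0 — pure
edema does not predict invasion), while the Pattern-C composite is strongly
associated with histological infiltration (ρ = 0.779, AUROC = 0.931). The
optimal operating point is a score of 2 — i.e. *at least one subsite with
Pattern C*: it identifies all 8 infiltrated patients (sensitivity 100%)
with 2 false positives among the 9 non-infiltrated (specificity 7/9 ≈ 78%).
Absence of Pattern C therefore argues strongly against a neoplastic cause
of the fixation.

The `examples/` directory holds short narrative scripts: analyzing the
reference cohort, scoring an external CSV, and validating estimator
recovery on simulated cohorts. A thin CLI wraps the same pipeline:

```bash
plcscore analyze --fixture table2 --out report/
plcscore simulate --preset table2-like --n 17 --seed 7 --out cohort.csv
```

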
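# Methods

## Data model

A cohort row is one patient: an identifier, seven MR signal-pattern codes
(one per PLC subsite, in the fixed order posterior vocal muscle, posterior
paraglottic space, inferior paraglottic space, arytenoid, cricoid lamina,
lateral cricoarytenoid muscle, cricothyroid muscle), and a binary
histological label (1 = neoplastic infiltration of the PLC/CAU). Pattern
codes form a closed three-letter alphabet A/B/C with the fixed ordinal map
A→0, B→1, C→2; CSV input accepts either encoding, output always writes
digits. Missing cells, out-of-alphabet codes, non-binary histology and
duplicate ids are hard errors with row/column context — the analysis has
no missing-data rule, so none is invented. One laterality-free code per
subsite is recorded, matching how the reference table is laid out.

## Composite scores

Per patient: Overall = Σ of the seven ordinal codes (0–14); Partial B =
sum restricted to codes equal to 1, i.e. the Pattern-B count (0–7);
Partial C = sum restricted to codes equal to 2, i.e. twice the Pattern-C
count (0–14, even). The decomposition Overall = Partial B + Partial C
holds identically and is enforced by the `ScoreTriple` type. Scores are
integers throughout; no floats, no alternative weightings.

## Statistical analysis

**Spearman correlation (tie-corrected).** Both variables are converted to
midranks (tied values share the mean of their rank span) and ρ is the
Pearson product-moment correlation of the midrank vectors — the standard
tie correction, which matters here because a binary label and small
integer scores are heavily tied. The 95% CI uses the Fisher
z-transform with standard error 1/√(n−3); the two-sided p-value uses the
t-approximation with n−2 degrees of freedom. On the reference cohort
these standard choices reproduce not only the published point estimates
but the published CIs and p-values to the printed precision, which
confirms the original analysis used the same formulas.

**AUROC.** Computed through the Mann–Whitney identity,
AUROC = (1/n₊n₋) Σ over positive–negative pairs of [1 if the positive
outscores the negative, ½ on ties], implemented via midranks in
O(n log n). This is algebraically identical to the trapezoidal area under
the empirical ROC curve with tied scores collapsed to single thresholds;
the identity is property-tested on random cohorts, and scikit-learn's
`roc_auc_score` serves as an additional independent oracle in the tests
(never as the implementation).

**ROC curve.** One point per distinct observed score under the rule
"test-positive ⇔ score ≥ threshold", plus the two degenerate endpoints
(sens 0/spec 1 at +∞, sens 1/spec 0 at −∞). The ≥ convention is what
makes "cutoff 2" mean "at least one Pattern-C subsite" on the even-valued
Partial C score.

**AUROC confidence intervals.** Default is DeLong's asymptotic interval on
the Mann–Whitney structural components (degenerate at perfect separation
after clipping to [0,1]); Hanley–McNeil's exponential approximation and a
patient-level percentile bootstrap (default B = 2000, explicit seed
required, single-class resamples redrawn) are selectable alternatives. The
originally published AUROC interval was produced by an unspecified method
that none of these reproduces exactly; intervals are therefore reported
with their method declared and are only required to contain the point
estimate.

**Cutoff selection.** Among observed score values, the threshold
maximizing Youden J = sensitivity + specificity − 1; ties in J are broken
toward the *smallest* threshold, i.e. the sensitivity-favoring operating
point — appropriate for a rule-out test whose clinical value is its
negative predictive power. The confusion table at the chosen threshold is
reported in full.

**Prevalence summary.** Patients are partitioned by worst pattern present:
all-A, B-only (≥1 B, no C), any-C; the any-C group is split by histology
into true/false positives of the "any Pattern C" rule. Percentages are
displayed rounded to the nearest integer; internal values keep full
precision. Significance is read at α = 0.05; p-values are descriptive
output, never inputs to any decision in the pipeline.

## Synthetic cohorts

The simulator draws, per patient, a Bernoulli(prevalence) infiltration
status, then one categorical A/B/C code per subsite from
status-conditional probability triples (defaults: (0.2, 0.3, 0.5) given
infiltration, (0.6, 0.3, 0.1) given none — a moderate-separation regime in
which the Pattern-C composite is informative but imperfect, resembling the
reference cohort qualitatively). An optional per-patient latent severity
z ~ N(0,1), scaled by `severity_coupling`, is added to the categorical
logits in proportion to the ordinal level before renormalization; higher
severity therefore tilts all seven subsites jointly and monotonically
toward C, inducing the within-patient clustering of C codes seen in real
data. One `numpy` Generator seeded per call; identical parameters give
bit-identical cohorts.

The `table2-like` preset estimates prevalence (8/17) and the per-subsite
conditional triples from the packaged cohort at call time, so a
17-patient demo cohort has realistic structure.

With `severity_coupling = 0` the subsites are conditionally independent
and the expected AUROC of the Partial C score is exact: convolve the seven
Bernoulli C-indicators into each class's 8-point score distribution and
enumerate P(S₊ > S₋) + ½P(S₊ = S₋). This closed form is the oracle for
recovery tests (empirical AUROC at n = 5000 within 0.02) and is itself
cross-checked against a direct binomial enumeration.

What the simulator does **not** emulate: reader variability (the pattern
codes are treated as ground-truth input, as in the source analysis, which
used consensus reading), laterality, subsite-specific anatomic
correlation structure beyond the single severity axis, and any link
between pattern probabilities and tumor stage. Passing recovery tests
shows the estimators are correct under the stated generative model, not
that the scoring system generalizes to other readers or scanners.

## Numerical choices

- Midranks via `scipy.stats.rankdata(method="average")`; rank sums are
  exact in floating point at these sizes.
- Spearman is undefined (and rejected) for constant inputs or n < 3;
  ρ = ±1 yields a degenerate CI at ±1 and p = 0.
- Youden tie-break tolerance 1e−12 on J; thresholds are exact integers
  here so ties are exact.
- CIs clipped to [0, 1] (AUROC) and [−1, 1] (implicitly, via tanh).
- Bootstrap redraws any resample that loses a class rather than skipping
  it, keeping B effective resamples; this slightly biases the interval
  toward two-class configurations and is documented behavior.

## Problem sizes

The reference analysis is 17 patients and runs in milliseconds. Simulation
tests use n = 5000 for recovery checks (sampling SE of AUROC ≈ 0.005
there, comfortably inside the 0.02 band) and n ≈ 3000 for the
correlation-structure check; the full suite completes in a few seconds.

## Limitations

- The packaged cohort is small (17 patients, 8 events); exact reproduction
  of its statistics is a correctness check on the pipeline, not evidence
  of clinical generalizability.
- The published AUROC CI method is unknown; see above.
- Pattern assignment is upstream human input: this package contains no
  image processing and cannot validate the radiologic codebook itself.
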
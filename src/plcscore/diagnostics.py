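"""Diagnostic-accuracy statistics for the composite pattern scores.

Implements the analysis pipeline applied to a scored cohort:

* tie-corrected Spearman rank correlation of each composite score against
  the binary histology label, with a Fisher-z confidence interval and a
  t-approximation p-value;
* the empirical ROC curve of the Pattern-C composite with AUROC computed
  through the Mann-Whitney pairwise identity (ties count one half);
* AUROC confidence intervals by DeLong (default), Hanley-McNeil, or a
  seeded patient-level bootstrap;
* Youden-index optimal cutoff with sensitivity, specificity and the full
  confusion table under the decision rule "positive if score >= cutoff";
* a pattern-prevalence summary (all-A patients, B-only patients, patients
  with at least one Pattern-C subsite, and how the latter split by
  histology).

All statistics are deterministic functions of the cohort except the
bootstrap interval, which takes an explicit seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import Cohort, Pattern
from .scoring import ScoreTable, score_cohort

__all__ = [
    "CorrelationResult",
    "RocCurve",
    "CutoffResult",
    "PatternPrevalenceSummary",
    "DiagnosticReport",
    "assign_midranks",
    "spearman",
    "roc_points",
    "auroc_mw",
    "auroc_ci",
    "best_cutoff_youden",
    "pattern_prevalence_summary",
    "run_full_analysis",
]


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    if not (y == 1).any():
        raise ValueError("no positive labels present")
    if not (y == 0).any():
        raise ValueError("no negative labels present")
    return s, y


def assign_midranks(values) -> np.ndarray:
    """Rank 1..n with tied values sharing the mean of their rank span.

    The rank sum is always n(n+1)/2.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty sequence")
    return stats.rankdata(values, method="average")


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation with a 95% Fisher-z interval and t-test p-value."""

    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {
            "rho": self.rho,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n": self.n,
        }


def spearman(x, y) -> CorrelationResult:
    """Tie-corrected Spearman correlation of two equal-length sequences.

    rho is the Pearson product-moment correlation of the two midrank
    vectors (the standard tie correction). The 95% interval uses the
    Fisher z-transform with standard error 1/sqrt(n-3); the two-sided
    p-value uses the t-approximation with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    rx, ry = assign_midranks(x), assign_midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    # Fisher z interval; degenerate at rho = +-1.
    if abs(rho) >= 1.0:
        ci_low = ci_high = float(np.sign(rho))
        p = 0.0
    else:
        z = np.arctanh(rho)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci_low, ci_high = float(np.tanh(z - half)), float(np.tanh(z + half))
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, ci_low=ci_low, ci_high=ci_high, p_value=p, n=n)


def auroc_mw(scores, labels) -> float:
    """AUROC via the Mann-Whitney pairwise identity.

    Averages, over all positive-negative pairs, 1 if the positive outscores
    the negative, 0.5 on a tie, 0 otherwise. Equals the trapezoidal area
    under the empirical ROC curve.
    """
    s, y = _as_arrays(scores, labels)
    pos, neg = s[y == 1], s[y == 0]
    # midrank formulation: O(n log n), exactly equal to pairwise counting
    ranks = assign_midranks(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class RocCurve:
    """Empirical ROC curve under the rule "positive if score >= threshold".

    ``points`` runs from the most stringent threshold (sens 0, spec 1,
    threshold +inf) to the loosest (sens 1, spec 0, threshold -inf), one
    point per distinct observed score in between.
    """

    points: list[tuple[float, float, float]]  # (threshold, sensitivity, specificity)
    auroc: float
    auroc_ci_low: float | None = None
    auroc_ci_high: float | None = None
    ci_method: str | None = None

    def trapezoid_area(self) -> float:
        """Area under the curve in (1-specificity, sensitivity) space."""
        fpr = np.array([1.0 - spec for _, _, spec in self.points])
        tpr = np.array([sens for _, sens, _ in self.points])
        order = np.argsort(fpr, kind="stable")
        return float(np.trapezoid(tpr[order], fpr[order]))

    def as_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "auroc_ci_low": self.auroc_ci_low,
            "auroc_ci_high": self.auroc_ci_high,
            "ci_method": self.ci_method,
            "points": [
                {"threshold": t, "sensitivity": se, "specificity": sp}
                for t, se, sp in self.points
            ],
        }

    def to_csv(self) -> str:
        lines = ["threshold,sensitivity,specificity"]
        lines += [f"{t},{se},{sp}" for t, se, sp in self.points]
        return "\n".join(lines) + "\n"


def _confusion_at(s: np.ndarray, y: np.ndarray, threshold: float) -> tuple[int, int, int, int]:
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return tp, fp, tn, fn


def roc_points(scores, labels) -> RocCurve:
    """Empirical ROC curve with one point per distinct observed score.

    Includes the two degenerate endpoints (sens 0 / spec 1 and
    sens 1 / spec 0). AUROC is attached via :func:`auroc_mw`.
    """
    s, y = _as_arrays(scores, labels)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    pts: list[tuple[float, float, float]] = [(float("inf"), 0.0, 1.0)]
    for t in sorted(np.unique(s), reverse=True):
        tp, fp, tn, fn = _confusion_at(s, y, t)
        pts.append((float(t), tp / n_pos, tn / n_neg))
    if pts[-1][1:] != (1.0, 0.0):
        pts.append((float("-inf"), 1.0, 0.0))
    return RocCurve(points=pts, auroc=auroc_mw(s, y))


def _delong_ci(s: np.ndarray, y: np.ndarray, alpha: float) -> tuple[float, float]:
    pos, neg = s[y == 1], s[y == 0]
    m, n = pos.size, neg.size
    theta = auroc_mw(s, y)
    # structural components via midranks (Sun & Xu formulation)
    all_ranks = assign_midranks(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - assign_midranks(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - assign_midranks(neg)) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(1 - alpha / 2)
    return float(np.clip(theta - z * se, 0, 1)), float(np.clip(theta + z * se, 0, 1))


def _hanley_mcneil_ci(s: np.ndarray, y: np.ndarray, alpha: float) -> tuple[float, float]:
    a = auroc_mw(s, y)
    m, n = int((y == 1).sum()), int((y == 0).sum())
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    var = (a * (1 - a) + (m - 1) * (q1 - a**2) + (n - 1) * (q2 - a**2)) / (m * n)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1 - alpha / 2)
    return float(np.clip(a - z * se, 0, 1)), float(np.clip(a + z * se, 0, 1))


def _bootstrap_ci(
    s: np.ndarray, y: np.ndarray, alpha: float, n_boot: int, seed: int
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = s.size
    vals = np.empty(n_boot)
    for b in range(n_boot):
        while True:  # redraw resamples that lose a class
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.any() and not yb.all():
                break
        vals[b] = auroc_mw(s[idx], yb)
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


def auroc_ci(
    scores,
    labels,
    method: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """95% (by default) confidence interval for the AUROC.

    methods: ``delong`` (default, asymptotic on the Mann-Whitney
    components), ``hanley_mcneil`` (exponential approximation), or
    ``bootstrap`` (percentile over patient-level resamples; single-class
    resamples are redrawn; requires a seed). Intervals are clipped to [0,1].
    """
    s, y = _as_arrays(scores, labels)
    if method == "delong":
        return _delong_ci(s, y, alpha)
    if method == "hanley_mcneil":
        return _hanley_mcneil_ci(s, y, alpha)
    if method == "bootstrap":
        if seed is None:
            raise ValueError("bootstrap CI requires an explicit seed")
        return _bootstrap_ci(s, y, alpha, n_boot, seed)
    raise ValueError(f"unknown CI method {method!r}")


@dataclass(frozen=True)
class CutoffResult:
    """Operating point at the Youden-optimal threshold (rule: score >= cutoff)."""

    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sensitivity_pct": round(100 * self.sensitivity),
            "specificity_pct": round(100 * self.specificity),
            "youden_j": self.youden_j,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


def best_cutoff_youden(scores, labels) -> CutoffResult:
    """Observed threshold maximizing Youden J = sensitivity + specificity - 1.

    Only finite observed score values are candidate thresholds. Ties in J
    are broken toward the smallest threshold, i.e. the sensitivity-favoring
    operating point of a rule-out test.
    """
    s, y = _as_arrays(scores, labels)
    thresholds = sorted(np.unique(s))
    if len(thresholds) < 2:
        raise ValueError("degenerate curve: all scores identical, no informative cutoff")
    best: CutoffResult | None = None
    for t in thresholds:
        tp, fp, tn, fn = _confusion_at(s, y, t)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        if best is None or j > best.youden_j + 1e-12:
            best = CutoffResult(float(t), sens, spec, j, tp, fp, tn, fn)
    assert best is not None
    return best


@dataclass(frozen=True)
class PatternPrevalenceSummary:
    """Cohort composition by worst pattern present in any subsite."""

    n: int
    n_all_pattern_a: int  # score 0 in every subsite
    n_b_only: int  # >=1 Pattern B, no Pattern C
    n_any_c: int  # >=1 Pattern C subsite
    n_true_pos: int  # among n_any_c, histology-positive
    n_false_pos: int  # among n_any_c, histology-negative
    n_histology_pos: int

    def as_dict(self) -> dict:
        pct = lambda k: round(100 * k / self.n)
        return {
            "n": self.n,
            "n_histology_pos": self.n_histology_pos,
            "histology_pos_pct": pct(self.n_histology_pos),
            "n_all_pattern_a": self.n_all_pattern_a,
            "all_pattern_a_pct": pct(self.n_all_pattern_a),
            "n_b_only": self.n_b_only,
            "b_only_pct": pct(self.n_b_only),
            "n_any_c": self.n_any_c,
            "any_c_pct": pct(self.n_any_c),
            "n_true_pos": self.n_true_pos,
            "n_false_pos": self.n_false_pos,
        }


def pattern_prevalence_summary(cohort: Cohort) -> PatternPrevalenceSummary:
    """Count patients by worst observed pattern, and split the any-C group
    by histology (true/false positives of the "any Pattern C" rule)."""
    cohort.require_nonempty()
    n_a = n_b = n_c = tp = fp = 0
    for r in cohort:
        pats = r.pattern_tuple()
        if any(p is Pattern.C for p in pats):
            n_c += 1
            if r.histology == 1:
                tp += 1
            else:
                fp += 1
        elif any(p is Pattern.B for p in pats):
            n_b += 1
        else:
            n_a += 1
    return PatternPrevalenceSummary(
        n=len(cohort),
        n_all_pattern_a=n_a,
        n_b_only=n_b,
        n_any_c=n_c,
        n_true_pos=tp,
        n_false_pos=fp,
        n_histology_pos=sum(cohort.histology),
    )


@dataclass
class DiagnosticReport:
    """Complete analysis output for one cohort."""

    n: int
    correlations: dict[str, CorrelationResult]
    roc: RocCurve
    cutoff: CutoffResult
    prevalence: PatternPrevalenceSummary
    scores: ScoreTable = field(repr=False)
    options: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "options": self.options,
            "correlations": {k: v.as_dict() for k, v in self.correlations.items()},
            "roc": self.roc.as_dict(),
            "cutoff": self.cutoff.as_dict(),
            "prevalence": self.prevalence.as_dict(),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.as_dict(), indent=indent)

    def summary_csv(self) -> str:
        """Flat one-row-per-quantity CSV summary."""
        rows = [("n", self.n)]
        for k, c in self.correlations.items():
            rows += [
                (f"spearman_rho_{k}", c.rho),
                (f"spearman_ci_low_{k}", c.ci_low),
                (f"spearman_ci_high_{k}", c.ci_high),
                (f"spearman_p_{k}", c.p_value),
            ]
        rows += [
            ("auroc_partial_c", self.roc.auroc),
            ("auroc_ci_low", self.roc.auroc_ci_low),
            ("auroc_ci_high", self.roc.auroc_ci_high),
            ("cutoff", self.cutoff.cutoff),
            ("sensitivity", self.cutoff.sensitivity),
            ("specificity", self.cutoff.specificity),
        ]
        return "\n".join(f"{k},{v}" for k, v in rows) + "\n"


def run_full_analysis(
    cohort: Cohort,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int | None = None,
) -> DiagnosticReport:
    """Score the cohort and run the full statistical analysis.

    Correlates each of the three composites with histology, builds the ROC
    curve of the Pattern-C composite with AUROC and its CI, finds the
    Youden-optimal cutoff, and summarizes pattern prevalence. Deterministic
    given the cohort unless ``ci_method='bootstrap'`` (then ``seed`` fixes
    the resamples).
    """
    cohort.require_nonempty()
    table = score_cohort(cohort)
    hist = table.histology
    if len(set(hist)) < 2:
        raise ValueError("analysis requires both histology classes in the cohort")

    correlations = {
        "overall": spearman(table.overall, hist),
        "partial_b": spearman(table.partial_b, hist),
        "partial_c": spearman(table.partial_c, hist),
    }
    curve = roc_points(table.partial_c, hist)
    lo, hi = auroc_ci(table.partial_c, hist, method=ci_method, n_boot=n_boot, seed=seed)
    curve.auroc_ci_low, curve.auroc_ci_high, curve.ci_method = lo, hi, ci_method
    cutoff = best_cutoff_youden(table.partial_c, hist)
    prevalence = pattern_prevalence_summary(cohort)
    options = {
        "roc_score": "partial_c",
        "decision_rule": "score >= threshold",
        "cutoff_tie_break": "smallest threshold (sensitivity-favoring)",
        "ci_method": ci_method,
        "alpha": 0.05,
    }
    if ci_method == "bootstrap":
        options.update({"n_boot": n_boot, "seed": seed})
    return DiagnosticReport(
        n=len(cohort),
        correlations=correlations,
        roc=curve,
        cutoff=cutoff,
        prevalence=prevalence,
        scores=table,
        options=options,
    )
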
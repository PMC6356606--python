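"""Statistical core: midranks, tie-corrected Spearman, Mann-Whitney AUROC,
ROC geometry, Youden cutoff, prevalence summary, and the report composition.

Each estimator is checked both against frozen values from the packaged
reference cohort and against an independent oracle (brute-force pairwise
enumeration, Pearson-on-midranks, scipy/sklearn reference routines).
"""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from plcscore import (
    assign_midranks,
    auroc_ci,
    auroc_mw,
    best_cutoff_youden,
    parse_cohort,
    pattern_prevalence_summary,
    roc_points,
    run_full_analysis,
    spearman,
    write_cohort,
)
from plcscore.simulate import SimParams, simulate_cohort


# ---------------------------------------------------------------- oracles
def midranks_bruteforce(values):
    """Independent midrank definition: count-below plus half the tie span."""
    return [
        sum(v < x for v in values) + (1 + sum(v == x for v in values)) / 2
        for x in values
    ]


def auroc_pairwise(scores, labels):
    """Exhaustive enumeration over all positive-negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return total / (len(pos) * len(neg))


# ------------------------------------------------- hypothesis strategies
@st.composite
def scored_cohort(draw, max_n=20, max_score=6):
    n = draw(st.integers(4, max_n))
    scores = draw(st.lists(st.integers(0, max_score), min_size=n, max_size=n))
    labels = draw(
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda ys: 0 < sum(ys) < len(ys)
        )
    )
    return scores, labels


# ---------------------------------------------------------------- midranks
class TestMidranks:
    def test_simple_tie(self):
        assert assign_midranks([0, 0, 2]).tolist() == [1.5, 1.5, 3.0]

    def test_singleton(self):
        assert assign_midranks([5]).tolist() == [1.0]

    def test_fixture_partial_c_column(self, fixture_scores):
        """Frozen midranks of the reference Pattern-C column (7 zeros -> 4,
        four 2s -> 9.5, two 4s -> 12.5, one 6 -> 14, two 8s -> 15.5, 10 -> 17)."""
        ranks = assign_midranks(fixture_scores.partial_c)
        expected = {0: 4.0, 2: 9.5, 4: 12.5, 6: 14.0, 8: 15.5, 10: 17.0}
        for value, rank in zip(fixture_scores.partial_c, ranks):
            assert rank == expected[value]

    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=30))
    def test_matches_bruteforce_definition_and_rank_sum(self, values):
        ranks = assign_midranks(values)
        assert np.allclose(ranks, midranks_bruteforce(values))
        n = len(values)
        assert np.isclose(ranks.sum(), n * (n + 1) / 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assign_midranks([])


# ---------------------------------------------------------------- spearman
class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,expected", [([1, 2, 3], [1, 2, 3], 1.0), ([1, 2, 3], [3, 2, 1], -1.0)]
    )
    def test_perfect_monotone(self, x, y, expected):
        assert spearman(x, y).rho == pytest.approx(expected)

    def test_fixture_correlations(self, fixture_scores):
        hist = fixture_scores.histology
        assert round(spearman(fixture_scores.partial_c, hist).rho, 3) == 0.779
        assert round(spearman(fixture_scores.overall, hist).rho, 3) == 0.690
        assert round(spearman(fixture_scores.partial_b, hist).rho, 4) == -0.0124

    def test_fixture_matches_scipy(self, fixture_scores):
        hist = fixture_scores.histology
        for col in (fixture_scores.overall, fixture_scores.partial_b,
                    fixture_scores.partial_c):
            ref = sps.spearmanr(col, hist)
            res = spearman(col, hist)
            assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    @given(scored_cohort(max_score=10))
    def test_equals_pearson_on_midranks_oracle(self, data):
        scores, labels = data
        if np.ptp(scores) == 0:
            return
        oracle = np.corrcoef(
            midranks_bruteforce(scores), midranks_bruteforce(labels)
        )[0, 1]
        assert spearman(scores, labels).rho == pytest.approx(oracle, abs=1e-12)

    def test_ci_brackets_rho(self, fixture_scores):
        r = spearman(fixture_scores.partial_c, fixture_scores.histology)
        assert r.ci_low <= r.rho <= r.ci_high

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [0, 1, 0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])


# ------------------------------------------------------------------- AUROC
class TestAuroc:
    def test_fixture_value_and_pairwise_fraction(self, fixture_scores):
        a = auroc_mw(fixture_scores.partial_c, fixture_scores.histology)
        assert round(a, 3) == 0.931
        assert a == pytest.approx(67 / 72, abs=1e-12)
        assert a == pytest.approx(
            auroc_pairwise(fixture_scores.partial_c, fixture_scores.histology)
        )

    def test_constant_scores_give_half(self):
        assert auroc_mw([3, 3, 3, 3], [0, 1, 0, 1]) == pytest.approx(0.5)

    def test_perfect_separation_gives_one(self):
        assert auroc_mw([0, 0, 5, 5], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive|negative"):
            auroc_mw([1, 2], [0, 0])

    @given(scored_cohort())
    def test_matches_pairwise_oracle_and_sklearn(self, data):
        scores, labels = data
        a = auroc_mw(scores, labels)
        assert a == pytest.approx(auroc_pairwise(scores, labels), abs=1e-12)
        assert a == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(scored_cohort())
    def test_label_flip_and_score_negation_antisymmetry(self, data):
        scores, labels = data
        a = auroc_mw(scores, labels)
        assert auroc_mw(scores, [1 - y for y in labels]) == pytest.approx(1 - a)
        assert auroc_mw([-s for s in scores], labels) == pytest.approx(1 - a)

    @given(scored_cohort(), st.randoms(use_true_random=False))
    def test_permutation_invariance(self, data, rnd):
        scores, labels = data
        order = list(range(len(scores)))
        rnd.shuffle(order)
        assert auroc_mw([scores[i] for i in order], [labels[i] for i in order]) == (
            pytest.approx(auroc_mw(scores, labels))
        )


# --------------------------------------------------------------- ROC curve
class TestRocCurve:
    def test_fixture_curve_contains_cutoff_point(self, fixture_scores):
        curve = roc_points(fixture_scores.partial_c, fixture_scores.histology)
        assert (2.0, 1.0, 7 / 9) in [
            (t, s, sp) for t, s, sp in curve.points
        ]

    def test_endpoints_present(self, fixture_scores):
        curve = roc_points(fixture_scores.partial_c, fixture_scores.histology)
        assert curve.points[0][1:] == (0.0, 1.0)
        assert curve.points[-1][1:] == (1.0, 0.0)

    def test_sensitivity_monotone_as_threshold_loosens(self, fixture_scores):
        curve = roc_points(fixture_scores.partial_c, fixture_scores.histology)
        sens = [s for _, s, _ in curve.points]
        assert sens == sorted(sens)

    def test_all_equal_scores_give_diagonal(self):
        curve = roc_points([1, 1, 1, 1], [0, 1, 0, 1])
        assert [(s, sp) for _, s, sp in curve.points] == [
            (0.0, 1.0), (1.0, 0.0)
        ]
        assert curve.auroc == pytest.approx(0.5)

    @given(scored_cohort())
    @settings(max_examples=60)
    def test_trapezoid_area_equals_mann_whitney(self, data):
        """The geometric AUROC (trapezoid under the empirical curve) must
        coincide with the pairwise Mann-Whitney statistic on every input."""
        scores, labels = data
        curve = roc_points(scores, labels)
        assert curve.trapezoid_area() == pytest.approx(curve.auroc, abs=1e-12)

    @given(scored_cohort())
    def test_confusion_counts_conserved_at_every_threshold(self, data):
        scores, labels = data
        from plcscore.diagnostics import _confusion_at

        s, y = np.asarray(scores, float), np.asarray(labels)
        for t in np.unique(s):
            tp, fp, tn, fn = _confusion_at(s, y, t)
            assert tp + fp + tn + fn == len(scores)
            assert tp + fn == sum(labels)


# --------------------------------------------------------------- AUROC CIs
class TestAurocCI:
    def test_delong_contains_estimate_on_fixture(self, fixture_scores):
        lo, hi = auroc_ci(fixture_scores.partial_c, fixture_scores.histology)
        a = auroc_mw(fixture_scores.partial_c, fixture_scores.histology)
        assert lo <= a <= hi
        assert 0.0 <= lo < hi <= 1.0

    def test_delong_degenerate_at_perfect_separation(self):
        lo, hi = auroc_ci([0, 0, 5, 5], [0, 0, 1, 1], method="delong")
        assert (lo, hi) == (1.0, 1.0)

    def test_hanley_contains_estimate(self, fixture_scores):
        lo, hi = auroc_ci(
            fixture_scores.partial_c, fixture_scores.histology, method="hanley_mcneil"
        )
        assert lo <= 67 / 72 <= hi

    def test_bootstrap_reproducible_under_seed(self, fixture_scores):
        kw = dict(method="bootstrap", n_boot=200, seed=42)
        ci1 = auroc_ci(fixture_scores.partial_c, fixture_scores.histology, **kw)
        ci2 = auroc_ci(fixture_scores.partial_c, fixture_scores.histology, **kw)
        assert ci1 == ci2
        assert ci1[0] <= 67 / 72 <= ci1[1] or ci1[1] >= 0.9  # percentile CI sanity

    def test_bootstrap_requires_seed(self, fixture_scores):
        with pytest.raises(ValueError, match="seed"):
            auroc_ci(fixture_scores.partial_c, fixture_scores.histology,
                     method="bootstrap")

    def test_unknown_method_rejected(self, fixture_scores):
        with pytest.raises(ValueError, match="unknown"):
            auroc_ci(fixture_scores.partial_c, fixture_scores.histology,
                     method="exact")


# ----------------------------------------------------------- Youden cutoff
class TestYoudenCutoff:
    def test_fixture_operating_point(self, fixture_scores):
        res = best_cutoff_youden(fixture_scores.partial_c, fixture_scores.histology)
        assert res.cutoff == 2.0
        assert res.sensitivity == pytest.approx(1.0)
        assert res.specificity == pytest.approx(7 / 9)
        assert round(100 * res.specificity) == 78
        assert (res.tp, res.fp, res.tn, res.fn) == (8, 2, 7, 0)
        assert res.youden_j == pytest.approx(res.sensitivity + res.specificity - 1)

    def test_perfect_separation_reaches_j_one(self):
        res = best_cutoff_youden([0, 0, 5, 5], [0, 0, 1, 1])
        assert res.youden_j == pytest.approx(1.0)
        assert res.cutoff == 5.0

    def test_tie_broken_toward_smallest_threshold(self):
        """scores (0,1,2,3) / labels (0,1,0,1): thresholds 1 and 3 both give
        J = 0.5; the sensitivity-favoring rule returns 1."""
        res = best_cutoff_youden([0, 1, 2, 3], [0, 1, 0, 1])
        assert res.cutoff == 1.0
        assert res.sensitivity == pytest.approx(1.0)

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            best_cutoff_youden([2, 2, 2], [0, 1, 1])

    @given(scored_cohort())
    def test_returned_j_is_global_maximum(self, data):
        scores, labels = data
        if np.ptp(scores) == 0:
            return
        res = best_cutoff_youden(scores, labels)
        pos = sum(labels)
        neg = len(labels) - pos
        js = []
        for t in sorted(set(scores)):
            tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
            fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
            js.append(tp / pos + (neg - fp) / neg - 1)
        assert res.youden_j == pytest.approx(max(js), abs=1e-12)


# ----------------------------------------------------- prevalence summary
class TestPrevalenceSummary:
    def test_fixture_counts(self, fixture_cohort):
        s = pattern_prevalence_summary(fixture_cohort)
        assert (s.n_all_pattern_a, s.n_b_only, s.n_any_c) == (1, 6, 10)
        assert (s.n_true_pos, s.n_false_pos) == (8, 2)
        d = s.as_dict()
        assert (d["all_pattern_a_pct"], d["b_only_pct"], d["any_c_pct"]) == (6, 35, 59)
        assert d["histology_pos_pct"] == 47

    def test_all_a_cohort(self):
        rows = "\n".join(f"p{i},0,0,0,0,0,0,0,0" for i in range(5))
        cohort = parse_cohort(
            "patient_id,post_vm,post_pgs,inf_pgs,ary,cric_lam,lcam,ctm,histology\n"
            + rows
        )
        s = pattern_prevalence_summary(cohort)
        assert (s.n_all_pattern_a, s.n_b_only, s.n_any_c) == (5, 0, 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_identity_on_simulated_cohorts(self, seed):
        cohort = simulate_cohort(SimParams(n_patients=40, prevalence=0.4, seed=seed))
        s = pattern_prevalence_summary(cohort)
        assert s.n_all_pattern_a + s.n_b_only + s.n_any_c == len(cohort)
        assert s.n_true_pos + s.n_false_pos == s.n_any_c


# ------------------------------------------------------------- full report
class TestFullAnalysis:
    def test_fixture_report_headline_numbers(self, fixture_cohort):
        rep = run_full_analysis(fixture_cohort)
        assert round(rep.correlations["partial_c"].rho, 3) == 0.779
        assert round(rep.correlations["overall"].rho, 3) == 0.690
        assert round(rep.correlations["partial_b"].rho, 4) == -0.0124
        assert round(rep.roc.auroc, 3) == 0.931
        assert rep.cutoff.cutoff == 2.0
        assert rep.cutoff.as_dict()["sensitivity_pct"] == 100
        assert rep.cutoff.as_dict()["specificity_pct"] == 78

    def test_report_deterministic_json(self, fixture_cohort):
        j1 = run_full_analysis(fixture_cohort).to_json()
        j2 = run_full_analysis(fixture_cohort).to_json()
        assert j1 == j2
        parsed = json.loads(j1)
        assert set(parsed) == {"n", "options", "correlations", "roc", "cutoff",
                               "prevalence"}

    def test_permutation_invariance_of_report(self, fixture_cohort):
        shuffled = parse_cohort(write_cohort(fixture_cohort))
        shuffled.records = shuffled.records[::-1]
        rep1 = run_full_analysis(fixture_cohort)
        rep2 = run_full_analysis(shuffled)
        assert rep1.roc.auroc == pytest.approx(rep2.roc.auroc)
        for k in rep1.correlations:
            assert rep1.correlations[k].rho == pytest.approx(
                rep2.correlations[k].rho
            )

    def test_single_class_cohort_rejected(self):
        rows = "\n".join(f"p{i},1,0,0,0,0,0,0,0" for i in range(4))
        cohort = parse_cohort(
            "patient_id,post_vm,post_pgs,inf_pgs,ary,cric_lam,lcam,ctm,histology\n"
            + rows
        )
        with pytest.raises(ValueError, match="class"):
            run_full_analysis(cohort)

    def test_simulated_cohort_yields_complete_report(self):
        cohort = simulate_cohort(SimParams(n_patients=60, prevalence=0.45, seed=5))
        rep = run_full_analysis(cohort)
        assert set(rep.correlations) == {"overall", "partial_b", "partial_c"}
        assert 0.0 <= rep.roc.auroc <= 1.0
        assert rep.prevalence.n == 60
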
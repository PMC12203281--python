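"""Assessment machinery: closed forms, rank statistics and the rubric."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hichkit import evaluation as ev
from hichkit import hws


def plan(diagnostic=(), surgical=False, rescue=(), drugs=()):
    items = set(diagnostic) | set(rescue) | set(drugs)
    if surgical:
        items.add(hws.SURGICAL_ITEM)
    bases = {i: [{"rule": "r", "text": "", "trace": []}] for i in items}
    return hws.TreatmentPlan(frozenset(diagnostic), surgical,
                             frozenset(rescue), frozenset(drugs), bases)


class TestClassificationMetrics:
    def test_balanced_counts_give_fifty_everywhere(self):
        m = ev.classification_metrics(ev.ConfusionCounts(25, 25, 25, 25))
        assert all(v == 50.0 for v in m.values())

    def test_hand_arithmetic_case(self):
        m = ev.classification_metrics(ev.ConfusionCounts(tp=90, fp=20, tn=80,
                                                         fn=10))
        assert m["sensitivity"] == pytest.approx(90.0)
        assert m["specificity"] == pytest.approx(80.0)
        assert m["accuracy"] == pytest.approx(85.0)
        assert m["ppv"] == pytest.approx(90 / 110 * 100)
        assert m["npv"] == pytest.approx(80 / 90 * 100)

    def test_perfect_classifier_all_hundred(self):
        m = ev.classification_metrics(ev.ConfusionCounts(10, 0, 10, 0))
        assert all(v == 100.0 for v in m.values())

    def test_zero_denominator_flagged_undefined_not_zero(self):
        m = ev.classification_metrics(ev.ConfusionCounts(tp=5, fp=0, tn=0, fn=0))
        assert m["specificity"] is None and m["npv"] is None
        assert m["sensitivity"] == 100.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.ConfusionCounts(-1, 0, 0, 1)


class TestRocAuc:
    def test_perfect_separation(self):
        assert ev.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert ev.roc_auc([3.0] * 6, [1, 0, 1, 0, 0, 1]) == 0.5

    def test_four_point_case_matches_all_pairs_count(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        wins = ties = 0
        for sp in (0.35, 0.8):
            for sn in (0.1, 0.4):
                wins += sp > sn
                ties += sp == sn
        expected = (wins + 0.5 * ties) / 4
        assert ev.roc_auc(scores, labels) == pytest.approx(expected)

    def test_single_class_is_contract_error(self):
        with pytest.raises(ValueError):
            ev.roc_auc([1.0, 2.0], [1, 1])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 16))
    def test_complementary_score_identity_and_sklearn_agreement(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, size=n).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        auc = ev.roc_auc(scores, labels)
        assert auc + ev.roc_auc(-scores, labels) == pytest.approx(1.0,
                                                                  abs=1e-12)
        from sklearn.metrics import roc_auc_score
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestCohensKappa:
    def test_diagonal_table_is_one(self):
        assert ev.cohens_kappa([[10, 0], [0, 7]]) == pytest.approx(1.0)

    def test_chance_level_table_is_zero(self):
        assert ev.cohens_kappa([[25, 25], [25, 25]]) == pytest.approx(0.0)

    def test_hand_computed_mixed_table(self):
        # p_o = 35/50 = 0.7 ; p_e = (25*30 + 25*20)/50^2 = 0.5 ; kappa = 0.4
        assert ev.cohens_kappa([[20, 5], [10, 15]]) == pytest.approx(0.4)

    def test_sklearn_agreement_on_random_ratings(self, rng):
        from sklearn.metrics import cohen_kappa_score
        for _ in range(10):
            a = rng.integers(0, 3, size=50)
            b = rng.integers(0, 3, size=50)
            table = ev.RaterTable.from_categories(a.tolist(), b.tolist(),
                                                  [0, 1, 2])
            assert ev.cohens_kappa(table) == \
                pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_kappa_never_exceeds_one_and_one_iff_diagonal(self, rng):
        for _ in range(20):
            t = rng.integers(0, 10, size=(3, 3)).astype(float)
            t += np.eye(3)  # ensure nonzero diagonal / nondegenerate margins
            try:
                k = ev.cohens_kappa(t)
            except ValueError:
                continue
            assert k <= 1.0 + 1e-12
            off = t.sum() - np.trace(t)
            assert (abs(k - 1.0) < 1e-12) == (off == 0)

    def test_degenerate_expected_agreement_is_error(self):
        with pytest.raises(ValueError):
            ev.cohens_kappa([[5, 0], [0, 0]])


class TestRubric:
    def gold(self):
        return plan(diagnostic=("repeat-head-ct", "coagulation-panel"),
                    surgical=True,
                    rescue=("vital-sign-monitoring", "venous-access",
                            "airway-clearance"),
                    drugs=("antihypertensive", "icp-lowering"))

    def test_identical_plans_score_configured_totals(self):
        g = self.gold()
        sc = ev.rubric_score(g, g)
        assert sc["total"] == 100.0
        assert sc["therapeutic"] == 85.0
        assert sc["diagnostic"] == 15.0

    def test_surgery_only_disagreement_costs_forty(self):
        g = self.gold()
        p = plan(diagnostic=g.diagnostic, surgical=False, rescue=g.rescue,
                 drugs=g.drugs)
        assert ev.rubric_score(p, g)["total"] == pytest.approx(60.0)

    def test_empty_prediction_scores_below_maxima(self):
        g = self.gold()
        sc = ev.rubric_score(plan(), g)
        assert sc["surgical"] == 0.0
        assert sc["diagnostic"] < 15 and sc["rescue"] < 35 and sc["drug"] < 10
        assert 0 <= sc["total"] <= 100

    def test_adding_a_correct_item_never_lowers_total(self):
        g = self.gold()
        partial = plan(diagnostic=("repeat-head-ct",), surgical=True,
                       rescue=("vital-sign-monitoring",), drugs=())
        better = plan(diagnostic=("repeat-head-ct", "coagulation-panel"),
                      surgical=True, rescue=("vital-sign-monitoring",),
                      drugs=())
        assert ev.rubric_score(better, g)["total"] >= \
            ev.rubric_score(partial, g)["total"]

    def test_unknown_item_is_taxonomy_error(self):
        g = self.gold()
        bad = hws.TreatmentPlan(diagnostic=frozenset({"crystal-ball"}),
                                bases={"crystal-ball": [{}]})
        with pytest.raises(ValueError):
            ev.rubric_score(bad, g)


class TestScoreDistribution:
    def test_all_perfect(self):
        assert ev.score_distribution([100.0] * 5) == (100.0, 0.0, 0.0)

    def test_three_way_split(self):
        top, mid, low = ev.score_distribution([90.0, 70.0, 50.0])
        assert top == pytest.approx(100 / 3)
        assert mid == pytest.approx(100 / 3)
        assert low == pytest.approx(100 / 3)
        assert top + mid + low == pytest.approx(100.0, abs=0.01)

    def test_empty_list_is_error_not_nan(self):
        with pytest.raises(ValueError):
            ev.score_distribution([])


class TestPooledAccuracy:
    def test_single_group_is_itself(self):
        assert ev.pooled_accuracy([(50, 91.3)]) == pytest.approx(91.3)

    def test_six_center_case_weighting(self):
        rows = [(216, 92.04), (128, 91.93), (95, 92.18), (73, 91.14),
                (62, 93.23), (31, 95.35)]
        assert ev.round2(ev.pooled_accuracy(rows)) == 92.22

    def test_equal_sizes_reduce_to_arithmetic_mean(self):
        rows = [(10, 80.0), (10, 90.0), (10, 100.0)]
        assert ev.pooled_accuracy(rows) == pytest.approx(90.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 16))
    def test_pooled_lies_within_group_range(self, seed):
        rng = np.random.default_rng(seed)
        rows = [(int(n), float(a)) for n, a in zip(
            rng.integers(1, 100, size=5), rng.uniform(0, 100, size=5))]
        pooled = ev.pooled_accuracy(rows)
        accs = [a for _, a in rows]
        assert min(accs) - 1e-9 <= pooled <= max(accs) + 1e-9


class TestF1FromPr:
    def test_equal_precision_recall_fixed_point(self):
        assert ev.f1_from_pr(77, 77) == pytest.approx(77.0)

    @pytest.mark.parametrize("p,r,expected", [
        (92.03, 90.22, 91.11), (98.53, 98.33, 98.43), (96.00, 77.00, 85.46)])
    def test_reported_pairs_to_two_decimals(self, p, r, expected):
        assert abs(ev.f1_from_pr(p, r) - expected) <= 0.01

    def test_zero_degenerate(self):
        assert ev.f1_from_pr(0, 0) == 0.0
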
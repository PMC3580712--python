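"""ROC/AUC machinery against brute-force and independent oracles."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from mtbench.roc_validation import (
    FIXED_CUTOFFS,
    SingleClassError,
    auc,
    auc_confidence_interval,
    classification_metrics,
    compare_aucs_ci_method,
    compare_aucs_z,
    delong_se,
    optimal_cutoff,
    performance_table,
    roc_curve,
    trapezoid_area,
)
from mtbench.synthetic_cohort import CohortSpec, generate_cohort

from conftest import make_record


def brute_force_auc(scores, outcomes):
    """Pairwise concordance enumeration (ties count one half)."""
    pos = [s for s, y in zip(scores, outcomes) if y]
    neg = [s for s, y in zip(scores, outcomes) if not y]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def random_instance(rng, max_n=30):
    """Random small scored sample with ties and both classes present."""
    n = int(rng.integers(4, max_n + 1))
    scores = rng.integers(0, 8, size=n).astype(float)  # ints force ties
    outcomes = rng.random(n) < 0.4
    if outcomes.all():
        outcomes[0] = False
    if not outcomes.any():
        outcomes[0] = True
    return scores, outcomes


class TestRocCurve:
    def test_perfect_separation(self):
        curve = roc_curve([10.0, 1.0], [True, False])
        assert curve.thresholds.tolist() == [-np.inf, 5.5, np.inf]
        assert curve.sensitivity[1] == 1.0
        assert curve.specificity[1] == 1.0

    def test_all_ties_reduces_to_sentinels(self):
        curve = roc_curve([3.0, 3.0, 3.0], [True, False, True])
        assert curve.thresholds.tolist() == [-np.inf, np.inf]
        assert trapezoid_area(curve) == pytest.approx(0.5)

    def test_hand_counted_curve(self):
        curve = roc_curve([3.0, 5.0, 1.0, 4.0],
                          [True, True, False, False])
        assert curve.thresholds.tolist() == [-np.inf, 2.0, 3.5, 4.5, np.inf]
        i = curve.thresholds.tolist().index(4.5)
        assert curve.sensitivity[i] == 0.5
        assert curve.specificity[i] == 1.0

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(5)
        s, y = random_instance(rng)
        curve = roc_curve(s, y)
        assert (curve.sensitivity[0], curve.specificity[0]) == (1.0, 0.0)
        assert (curve.sensitivity[-1], curve.specificity[-1]) == (0.0, 1.0)
        assert (np.diff(curve.sensitivity) <= 0).all()
        assert (np.diff(curve.specificity) >= 0).all()

    def test_single_class_is_an_error(self):
        with pytest.raises(SingleClassError):
            roc_curve([1.0, 2.0], [True, True])


class TestAuc:
    def test_textbook_cases(self):
        assert auc([10, 1], [True, False]) == 1.0
        assert auc([3, 3, 3], [True, False, True]) == 0.5
        assert auc([3, 5, 1, 4], [True, True, False, False]) == 0.75

    def test_equals_pairwise_enumeration_and_trapezoid(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            s, y = random_instance(rng)
            a = auc(s, y)
            assert a == pytest.approx(brute_force_auc(s, y), abs=1e-12)
            assert a == pytest.approx(trapezoid_area(roc_curve(s, y)),
                                      abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            s, y = random_instance(rng)
            assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariance_and_reversal(self):
        rng = np.random.default_rng(9)
        s, y = random_instance(rng)
        assert auc(np.exp(s / 3.0), y) == pytest.approx(auc(s, y), abs=1e-12)
        assert auc(-s, y) == pytest.approx(1.0 - auc(s, y), abs=1e-12)


class TestConfidenceIntervals:
    def test_hanley_mcneil_closed_form(self):
        # AUC .75 with 2 cases / 2 controls: Q1=.6, Q2=.642857, SE=.27630
        s = [3.0, 5.0, 1.0, 4.0]
        y = [True, True, False, False]
        lo, hi = auc_confidence_interval(s, y, method="hanley_mcneil")
        assert lo == pytest.approx(0.75 - 1.959964 * 0.276304, abs=2e-4)
        assert hi == 1.0  # clipped

    def test_perfect_separation_clips_at_one(self):
        s = list(range(100))
        y = [v >= 50 for v in s]
        for method in ("hanley_mcneil", "delong"):
            _, hi = auc_confidence_interval(s, y, method=method)
            assert hi == 1.0

    def test_delong_and_bootstrap_agree_on_moderate_sample(self):
        rng = np.random.default_rng(2024)
        y = rng.random(500) < 0.3
        s = rng.standard_normal(500) + 1.2 * y
        lo_d, hi_d = auc_confidence_interval(s, y, method="delong")
        lo_b, hi_b = auc_confidence_interval(
            s, y, method="bootstrap", n_bootstrap=10000, seed=11)
        assert lo_b == pytest.approx(lo_d, abs=0.02)
        assert hi_b == pytest.approx(hi_d, abs=0.02)

    def test_bootstrap_needs_two_per_class(self):
        with pytest.raises(ValueError):
            auc_confidence_interval([1.0, 2.0], [True, False],
                                    method="bootstrap", seed=0)

    def test_bootstrap_is_seeded(self):
        rng = np.random.default_rng(1)
        s, y = random_instance(rng)
        a = auc_confidence_interval(s, y, method="bootstrap", seed=42)
        b = auc_confidence_interval(s, y, method="bootstrap", seed=42)
        assert a == b


class TestCompareAucs:
    def test_identical_curves_give_p_one(self):
        assert compare_aucs_ci_method(
            0.8, (0.7, 0.9), 0.8, (0.7, 0.9)) == pytest.approx(1.0)

    def test_published_tash_vs_pwh_rows(self):
        # AUC .889 (CI .871-.907) vs .860 (CI .839-.881): z ~ 2.055,
        # two-sided p ~ 0.040, consistent with the published 0.0413 up to
        # rounding of the printed AUCs/CIs
        z = compare_aucs_z(0.889, (0.871, 0.907), 0.860, (0.839, 0.881))
        p = compare_aucs_ci_method(0.889, (0.871, 0.907),
                                   0.860, (0.839, 0.881))
        assert z == pytest.approx(2.055, abs=0.01)
        assert 0.035 < p < 0.045

    def test_closed_form_example(self):
        p = compare_aucs_ci_method(0.90, (0.80, 1.00), 0.85, (0.75, 0.95))
        z = compare_aucs_z(0.90, (0.80, 1.00), 0.85, (0.75, 0.95))
        assert z == pytest.approx(0.693, abs=0.005)
        assert p == pytest.approx(0.488, abs=0.005)

    def test_symmetric_in_arguments(self):
        p1 = compare_aucs_ci_method(0.9, (0.85, 0.95), 0.8, (0.7, 0.9))
        p2 = compare_aucs_ci_method(0.8, (0.7, 0.9), 0.9, (0.85, 0.95))
        assert p1 == pytest.approx(p2, abs=1e-15)

    def test_p_tends_to_one_as_difference_vanishes(self):
        ps = [compare_aucs_ci_method(0.8 + d, (0.75 + d, 0.85 + d),
                                     0.8, (0.75, 0.85))
              for d in (0.10, 0.05, 0.01, 0.001)]
        assert ps == sorted(ps)
        assert ps[-1] > 0.95

    def test_asymmetric_interval_rejected(self):
        with pytest.raises(ValueError):
            compare_aucs_ci_method(0.95, (0.85, 1.0), 0.8, (0.7, 0.9))


class TestOptimalCutoff:
    def brute_force(self, s, y):
        curve = roc_curve(s, y)
        best, best_j = None, -np.inf
        for t, sn, sp in zip(curve.thresholds[1:-1],
                             curve.sensitivity[1:-1],
                             curve.specificity[1:-1]):
            j = sn + sp - 1.0
            if j > best_j:
                best, best_j = t, j
        return best

    def test_perfect_separation(self):
        curve = roc_curve([10.0, 1.0], [True, False])
        assert optimal_cutoff(curve) == 5.5

    def test_tie_breaks_toward_higher_sensitivity(self):
        s = [8.0, 9.0, 10.0, 1.0, 2.0, 9.0]
        y = [True, True, True, False, False, False]
        assert optimal_cutoff(roc_curve(s, y)) == 5.0

    def test_half_point_cutoff_on_integer_scores(self):
        s = [9.0, 10.0, 11.0, 3.0, 5.0, 8.0]
        y = [True, True, True, False, False, False]
        assert optimal_cutoff(roc_curve(s, y)) == 8.5

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            s, y = random_instance(rng)
            curve = roc_curve(s, y)
            assert optimal_cutoff(curve) == self.brute_force(s, y)

    def test_degenerate_curve_is_an_error(self):
        with pytest.raises(ValueError):
            optimal_cutoff(roc_curve([2.0, 2.0], [True, False]))


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        m = classification_metrics([9, 8, 1, 2], [True, True, False, False],
                                   5.0)
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1, 1, 1, 1)

    def test_hand_confusion_matrix(self):
        m = classification_metrics([9, 3, 2, 8], [True, True, False, False],
                                   5.0)
        assert (m.tp, m.fn, m.fp, m.tn) == (1, 1, 1, 1)
        assert m.sensitivity == m.specificity == m.ppv == m.npv == 0.5

    def test_threshold_above_all_scores(self):
        m = classification_metrics([3, 2, 1], [True, False, False], 10.0)
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0
        assert m.ppv is None  # empty positive cell stays undefined

    def test_counts_always_consistent(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            s, y = random_instance(rng)
            t = float(rng.uniform(-1, 9))
            m = classification_metrics(s, y, t)
            assert m.tp + m.fp + m.tn + m.fn == len(s)
            if m.sensitivity is not None:
                assert m.sensitivity * (m.tp + m.fn) == pytest.approx(m.tp)
            if m.specificity is not None:
                assert m.specificity * (m.tn + m.fp) == pytest.approx(m.tn)


class TestPerformanceTable:
    @pytest.fixture(scope="class")
    def cohort(self):
        return generate_cohort(CohortSpec(n=3000, seed=17))

    def test_deterministic_given_fixed_cohort(self, cohort):
        t1, _ = performance_table(cohort)
        t2, _ = performance_table(cohort)
        assert t1.equals(t2)

    def test_fixed_mode_uses_published_cutoffs(self, cohort):
        table, _ = performance_table(cohort, cutoff_mode="fixed")
        got = dict(zip(table["score"], table["cutoff"]))
        assert got == FIXED_CUTOFFS

    def test_all_aucs_beat_chance_and_weighted_scores_lead(self, cohort):
        table, _ = performance_table(cohort)
        assert (table["auc"] > 0.5).all()
        by = table.set_index("score")["auc"]
        assert by["tash"] > by["abc"]

    def test_tash_beats_abc_across_seeds(self):
        wins = 0
        for seed in range(5):
            cohort = generate_cohort(CohortSpec(n=2000, seed=seed))
            table, _ = performance_table(cohort, ci_method="hanley_mcneil")
            by = table.set_index("score")["auc"]
            wins += by["tash"] > by["abc"]
        assert wins >= 4  # latent severity rewards weighted multi-variable scores

    def test_hand_fixture_row(self):
        cohort = [
            make_record("mt1", sbp_er=85.0, heart_rate_er=125.0,
                        fast_positive=True, prbc_units_er_to_icu=15),
            make_record("mt2", prbc_units_er_to_icu=12),
            make_record("c1"), make_record("c2"),
            make_record("c3", sbp_er=88.0),
        ]
        table, _ = performance_table(cohort, score_ids=["abc"],
                                     cutoff_mode="fixed",
                                     ci_method="hanley_mcneil")
        row = table.iloc[0]
        # abc scores: 3,0 | 0,0,1 at cutoff 0.5 -> TP=1 FN=1 FP=1 TN=2
        assert (row.tp, row.fn, row.fp, row.tn) == (1, 1, 1, 2)
        assert row.sensitivity_pct == pytest.approx(50.0)
        assert row.specificity_pct == pytest.approx(200 / 3)
        assert row.ppv_pct == pytest.approx(50.0)
        assert row.npv_pct == pytest.approx(200 / 3)

    def test_roc_coordinate_files(self, cohort, tmp_path):
        performance_table(cohort, score_ids=["tash"], roc_dir=tmp_path)
        text = (tmp_path / "roc_tash.csv").read_text()
        assert text.splitlines()[0] == (
            "threshold,sensitivity,one_minus_specificity")

    def test_unknown_score_id(self, cohort):
        with pytest.raises(KeyError):
            performance_table(cohort, score_ids=["bogus"])

    def test_delong_se_matches_hanley_order_of_magnitude(self, cohort):
        # sanity: the two SE estimators agree to within a factor ~1.5
        from mtbench.scores import score_cohort
        matrix = score_cohort(cohort, ["tash"])
        s = matrix["tash"].to_numpy(float)
        y = matrix["mt_outcome"].to_numpy(bool)
        lo_d, hi_d = auc_confidence_interval(s, y, method="delong")
        lo_h, hi_h = auc_confidence_interval(s, y, method="hanley_mcneil")
        assert (hi_d - lo_d) == pytest.approx(hi_h - lo_h, rel=0.5)
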
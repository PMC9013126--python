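import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from pcr_radiomics import errors
from pcr_radiomics.evaluation import (
    ConfusionMatrix,
    auc,
    auc_ci,
    cohens_kappa,
    cohens_kappa_ci,
    compare_cohorts,
    confusion_at_threshold,
    reconstruct_confusion_matrix,
    roc_points,
    subgroup_validation,
    threshold_metrics,
    validate_cohort,
    youden_index,
    youden_threshold,
)

TABLE3_WHOLE = {"accuracy": 0.65, "specificity": 0.64, "sensitivity": 0.70,
                "npv": 0.91, "ppv": 0.28}


def _brute_force_auc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def _random_fixture(rng, n_max=50):
    n = int(rng.integers(4, n_max + 1))
    scores = rng.choice(rng.normal(size=max(2, n // 2)), size=n)  # force ties
    labels = np.zeros(n, int)
    labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
    if labels.sum() in (0, n):
        labels[0], labels[-1] = 0, 1
    return scores, labels


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 0, 0]) == 0.5

    def test_four_pair_example(self):
        # positives {0.9, 0.4}, negatives {0.5, 0.1}: 3 of 4 pairs concordant
        assert auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_single_class_raises(self):
        with pytest.raises(errors.DegenerateCohortError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_small_fixtures(self, rng):
        for _ in range(50):
            s, y = _random_fixture(rng, n_max=20)
            assert auc(s, y) == pytest.approx(_brute_force_auc(s, y), abs=1e-12)

    def test_matches_trapezoidal_roc_integration(self, rng):
        for _ in range(100):
            s, y = _random_fixture(rng, n_max=50)
            roc = roc_points(s, y)
            trap = np.trapezoid(roc[:, 1], roc[:, 0])
            assert auc(s, y) == pytest.approx(trap, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        for _ in range(25):
            s, y = _random_fixture(rng)
            assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_score_flip_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        s, y = _random_fixture(rng)
        assert auc(s, y) + auc(-np.asarray(s), y) == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_invariant_under_strictly_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        s, y = _random_fixture(rng)
        assert auc(np.exp(s), y) == pytest.approx(auc(s, y), abs=1e-12)


class TestAucCI:
    def test_interval_contains_point_estimate(self, validation_like_cohort):
        df = validation_like_cohort
        s, y = df["score"].to_numpy(), df["pcr_label"].to_numpy()
        a = auc(s, y)
        lo, hi = auc_ci(s, y)
        assert lo <= a <= hi

    def test_perfect_separation_clips_at_one(self, rng):
        s = np.concatenate([rng.uniform(0.6, 1.0, 50), rng.uniform(0.0, 0.4, 50)])
        y = np.array([1] * 50 + [0] * 50)
        lo, hi = auc_ci(s, y)
        assert hi == 1.0

    def test_99_interval_contains_95_interval(self, validation_like_cohort):
        df = validation_like_cohort
        s, y = df["score"].to_numpy(), df["pcr_label"].to_numpy()
        lo95, hi95 = auc_ci(s, y, level=0.95)
        lo99, hi99 = auc_ci(s, y, level=0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_delong_variance_close_to_bootstrap(self, validation_like_cohort):
        """DeLong SE and a 2000-rep bootstrap agree within 20% on n=59."""
        df = validation_like_cohort
        s, y = df["score"].to_numpy(), df["pcr_label"].to_numpy()
        z = stats.norm.ppf(0.975)
        lo, hi = auc_ci(s, y, method="delong")
        se_delong = (hi - lo) / (2 * z)
        rng = np.random.default_rng(3)
        pos, neg = s[y == 1], s[y == 0]
        boots = [
            auc(
                np.concatenate([rng.choice(pos, pos.size), rng.choice(neg, neg.size)]),
                np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)]),
            )
            for _ in range(2000)
        ]
        se_boot = np.std(boots)
        assert se_delong == pytest.approx(se_boot, rel=0.2)

    def test_too_few_per_class_raises(self):
        with pytest.raises(errors.DegenerateCohortError):
            auc_ci([0.1, 0.5, 0.9], [1, 0, 0])


class TestYouden:
    def test_printed_sensitivity_specificity_pair(self):
        # the original-model operating point: sens 0.76, spec 0.63
        assert youden_index(0.76, 0.63) == pytest.approx(0.39)

    def test_perfect_separation_gives_j_of_one(self):
        t, j, sens, spec = youden_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert j == 1.0 and sens == 1.0 and spec == 1.0
        assert t == 0.8  # lowest threshold attaining the maximum

    def test_labels_independent_of_scores_give_near_zero_j(self):
        rng = np.random.default_rng(1)
        n = 10_000
        s = rng.uniform(size=n)
        y = rng.integers(0, 2, size=n)
        _, j, _, _ = youden_threshold(s, y)
        assert j < 0.1

    def test_tie_break_toward_lower_threshold(self):
        # thresholds 0.2 and 0.4 both give J = 0.5; the lower must win
        s = [0.1, 0.2, 0.4, 0.5]
        y = [0, 1, 0, 1]
        t, j, _, _ = youden_threshold(s, y)
        assert j == pytest.approx(0.5)
        assert t == 0.2


class TestConfusionMatrix:
    def test_zero_threshold_calls_everything_positive(self):
        cm = confusion_at_threshold([0.2, 0.7, 0.5], [1, 0, 1], 0.0)
        assert cm.fn == 0 and cm.tn == 0 and cm.n == 3

    def test_threshold_above_max_calls_everything_negative(self):
        cm = confusion_at_threshold([0.2, 0.7, 0.5], [1, 0, 1], 0.8)
        assert cm.tp == 0 and cm.fp == 0

    def test_hand_counted_fixture(self):
        scores = [0.9, 0.6, 0.3, 0.8, 0.1, 0.45]
        labels = [1, 0, 1, 1, 0, 0]
        cm = confusion_at_threshold(scores, labels, 0.5)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 1, 1, 2)

    def test_boundary_counts_as_positive_call(self):
        cm = confusion_at_threshold([0.267], [0], 0.267)
        assert cm.fp == 1

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fn=0, fp=0, tn=1)


class TestThresholdMetrics:
    def test_reconstructed_whole_cohort_metrics(self):
        cm = ConfusionMatrix(tp=7, fn=3, fp=18, tn=31)
        m = threshold_metrics(cm)
        assert round(m["npv"].value, 2) == 0.91
        assert round(m["ppv"].value, 2) == 0.28
        assert round(m["sensitivity"].value, 2) == 0.70

    def test_perfect_matrix_gives_all_ones(self):
        m = threshold_metrics(ConfusionMatrix(tp=10, fn=0, fp=0, tn=49))
        assert all(m[k].value == 1.0 for k in m)

    def test_cis_contain_their_point_estimates(self):
        m = threshold_metrics(ConfusionMatrix(tp=7, fn=3, fp=18, tn=31))
        for est in m.values():
            lo, hi = est.ci
            assert lo <= est.value <= hi

    def test_zero_denominator_reported_as_undefined(self):
        # no positive calls -> PPV denominator is 0
        m = threshold_metrics(ConfusionMatrix(tp=0, fn=5, fp=0, tn=10))
        assert m["ppv"].value is None
        assert "denominator" in m["ppv"].undefined_reason
        assert m["accuracy"].value is not None

    def test_accuracy_decomposition_identity(self, rng):
        """accuracy = sens * prevalence + spec * (1 - prevalence), exactly."""
        for _ in range(50):
            tp, fn, fp, tn = rng.integers(1, 40, size=4)
            cm = ConfusionMatrix(int(tp), int(fn), int(fp), int(tn))
            m = threshold_metrics(cm)
            prev = cm.n_positive / cm.n
            lhs = m["accuracy"].value
            rhs = m["sensitivity"].value * prev + m["specificity"].value * (1 - prev)
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_clopper_pearson_coverage_at_nominal(self):
        """CP intervals are conservative: coverage >= 95% at n=34, p=0.9."""
        n, p, reps = 34, 0.9, 10_000
        rng = np.random.default_rng(17)
        k = rng.binomial(n, p, size=reps)
        lo = np.where(k > 0, stats.beta.ppf(0.025, k, n - k + 1), 0.0)
        hi = np.where(k < n, stats.beta.ppf(0.975, k + 1, n - k), 1.0)
        coverage = np.mean((lo <= p) & (p <= hi))
        assert coverage >= 0.95
        # spot-check our implementation against the simulated formula
        m = threshold_metrics(ConfusionMatrix(tp=0, fn=0, fp=int(n - k[0]), tn=int(k[0])))
        est = m["specificity"]
        i = 0
        assert est.ci == pytest.approx((lo[i], hi[i]), abs=1e-12)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(ConfusionMatrix(tp=10, fn=0, fp=0, tn=49)) == 1.0

    def test_whole_cohort_value(self):
        # p_o = 38/59, p_e = 1916/3481 -> kappa = 326/1565
        k = cohens_kappa(ConfusionMatrix(tp=7, fn=3, fp=18, tn=31))
        assert k == pytest.approx(0.208, abs=1e-3)

    def test_independent_margins_give_zero(self):
        # margins factorise: rows (10, 90), calls (20, 80) -> tp = 2 etc.
        assert cohens_kappa(ConfusionMatrix(tp=2, fn=8, fp=18, tn=72)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn(self, rng):
        for _ in range(20):
            tp, fn, fp, tn = (int(v) for v in rng.integers(1, 30, size=4))
            truth = [1] * (tp + fn) + [0] * (fp + tn)
            pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
            cm = ConfusionMatrix(tp, fn, fp, tn)
            assert cohens_kappa(cm) == pytest.approx(cohen_kappa_score(truth, pred), abs=1e-12)

    def test_ci_contains_point_estimate(self):
        cm = ConfusionMatrix(tp=7, fn=3, fp=18, tn=31)
        lo, hi = cohens_kappa_ci(cm)
        assert lo <= cohens_kappa(cm) <= hi

    def test_degenerate_marginals_raise(self):
        with pytest.raises(errors.UndefinedKappaError):
            cohens_kappa(ConfusionMatrix(tp=5, fn=0, fp=0, tn=0))


class TestReconstruction:
    def test_whole_cohort_column_is_unique(self):
        cm = reconstruct_confusion_matrix(59, 10, TABLE3_WHOLE)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (7, 3, 18, 31)

    def test_self_consistent_column_inverts_exactly(self):
        target = ConfusionMatrix(tp=6, fn=4, fp=10, tn=39)
        printed = {k: round(v.value, 2) for k, v in threshold_metrics(target).items()}
        cm = reconstruct_confusion_matrix(59, 10, printed)
        assert cm == target

    def test_impossible_column_raises(self):
        bad = {"sensitivity": 0.99, "specificity": 0.99, "accuracy": 0.2,
               "npv": 0.01, "ppv": 0.01}
        with pytest.raises(errors.ReconstructionError):
            reconstruct_confusion_matrix(59, 10, bad)

    def test_ambiguous_column_lists_candidates(self):
        # sensitivity alone cannot pin down FP/TN
        with pytest.raises(errors.ReconstructionError) as exc:
            reconstruct_confusion_matrix(59, 10, {"sensitivity": 0.70})
        assert len(exc.value.candidates) > 1

    def test_unknown_metric_name_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_confusion_matrix(59, 10, {"f1": 0.5})


class TestCohortComparison:
    def test_t_stage_counts_reproduce_printed_p(self):
        _, p = compare_cohorts([15, 95, 52], [6, 34, 19], kind="categorical")
        assert round(p, 2) == 0.98

    def test_sex_counts_reproduce_printed_p(self):
        _, p = compare_cohorts([123, 39], [47, 12], kind="categorical")
        assert round(p, 2) == 0.56

    def test_identical_rows_give_zero_statistic(self):
        chi2, p = compare_cohorts([10, 20, 30], [10, 20, 30], kind="categorical")
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_expected_cell_raises(self):
        with pytest.raises(errors.InvalidTableError):
            compare_cohorts([0, 10], [0, 20], kind="categorical")

    def test_continuous_uses_mann_whitney(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(1.5, 1, 40)
        u, p = compare_cohorts(a, b, kind="continuous")
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert (u, p) == (ref.statistic, ref.pvalue)
        assert p < 0.01


class TestValidationReports:
    def test_both_threshold_blocks_present(self, validation_like_cohort, model_spec):
        df = validation_like_cohort
        rep = validate_cohort(df["score"], df["pcr_label"], model_spec.threshold)
        labels = [b.label for b in rep.blocks]
        assert labels[0] == "published"
        assert "youden-local" in labels
        assert rep.blocks[0].threshold == 0.267

    def test_report_rates_and_cis_are_well_formed(self, validation_like_cohort, model_spec):
        df = validation_like_cohort
        rep = validate_cohort(df["score"], df["pcr_label"], model_spec.threshold)
        d = rep.to_dict()
        assert d["auc_ci"][0] <= d["auc"] <= d["auc_ci"][1]
        for block in d["blocks"]:
            for m in block["metrics"].values():
                if m["value"] is not None:
                    assert 0.0 <= m["value"] <= 1.0
                    assert m["ci"][0] <= m["value"] <= m["ci"][1]

    def test_identical_subgroups_get_identical_reports(self, validation_like_cohort, model_spec):
        df = validation_like_cohort
        s = np.tile(df["score"].to_numpy(), 2)
        y = np.tile(df["pcr_label"].to_numpy(), 2)
        g = np.repeat(["a", "b"], len(df))
        rep = subgroup_validation(s, y, g, model_spec.threshold)
        ra, rb = rep.subgroups["a"].to_dict(), rep.subgroups["b"].to_dict()
        assert ra == rb

    def test_single_class_subgroup_flagged_not_fatal(self, model_spec, rng):
        s = rng.uniform(size=40)
        y = np.array([1] * 5 + [0] * 15 + [0] * 20)  # group b has no positives
        g = np.array(["a"] * 20 + ["b"] * 20)
        rep = subgroup_validation(s, y, g, model_spec.threshold)
        assert rep.subgroups["b"].auc is None
        assert any("AUC undefined" in f for f in rep.subgroups["b"].flags)
        assert rep.subgroups["a"].auc is not None

    def test_group_independent_scores_give_similar_subgroup_aucs(self, model_spec):
        rng = np.random.default_rng(8)
        n = 1000
        y = rng.integers(0, 2, n)
        s = np.clip(0.5 + 0.25 * (y - 0.5) + 0.2 * rng.standard_normal(n), 0, 1)
        g = np.repeat(["g1", "g2"], n // 2)  # groups independent of scores
        rep = subgroup_validation(s, y, g, model_spec.threshold)
        for key in ("g1", "g2"):
            assert rep.subgroups[key].auc == pytest.approx(rep.auc, abs=0.1)

    def test_pooled_thresholds_applied_to_subgroups(self, validation_like_cohort, model_spec):
        df = validation_like_cohort
        rep = subgroup_validation(
            df["score"].to_numpy(), df["pcr_label"].to_numpy(),
            df["field_strength"].to_numpy(), model_spec.threshold)
        pooled_youden = {b.label: b.threshold for b in rep.blocks}["youden-local"]
        for sub in rep.subgroups.values():
            by_label = {b.label: b.threshold for b in sub.blocks}
            assert by_label["published"] == model_spec.threshold
            assert by_label["youden-local"] == pooled_youden
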
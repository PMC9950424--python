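import itertools

import numpy as np
import pandas as pd
import pytest

from adprog.evaluation import (
    auroc,
    conversion_error_analysis,
    loso_split,
    net_benefit,
    reliability_diagrams,
)
from adprog.synthetic import GeneratorConfig, generate_cohort


def auroc_bruteforce(scores, labels):
    """Exhaustive concordant-pair counting with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestLosoSplit:
    def test_three_sites_three_folds(self):
        cohort, _ = generate_cohort(GeneratorConfig(n_subjects=15, n_sites=3, seed=1))
        folds = loso_split(cohort)
        assert len(folds) == 3
        assert {test for _, test in folds} == set(cohort.sites)

    def test_folds_partition_subjects(self):
        cohort, _ = generate_cohort(GeneratorConfig(n_subjects=24, n_sites=4, seed=2))
        seen = []
        cov = cohort.covariates
        for train_sites, test_site in loso_split(cohort):
            test_ids = set(cov.loc[cov["site_id"] == test_site, "subject_id"])
            train_ids = set(cov.loc[cov["site_id"].isin(train_sites), "subject_id"])
            assert not test_ids & train_ids
            seen.extend(test_ids)
        assert sorted(seen) == sorted(cohort.subject_ids)

    def test_twelve_site_cohort_yields_twelve_folds(self):
        cohort, _ = generate_cohort(GeneratorConfig(n_subjects=60, n_sites=12, seed=3))
        assert len(loso_split(cohort)) == 12

    def test_single_site_suggests_fallback(self):
        cohort, _ = generate_cohort(GeneratorConfig(n_subjects=6, n_sites=1, seed=4))
        with pytest.raises(ValueError, match="k-fold"):
            loso_split(cohort)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_worked_four_point_example(self):
        assert auroc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 51)
        scores = rng.choice(np.round(rng.random(8), 2), size=n)  # induce ties
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert auroc(scores, labels) == pytest.approx(auroc_bruteforce(scores, labels), abs=1e-12)

    def test_cross_checked_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        scores = rng.random(200)
        labels = rng.random(200) < 0.3
        assert auroc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            auroc([0.1, 0.2], [1, 1])


class TestReliability:
    def test_certain_correct_predictions_fill_top_bin(self):
        preds = pd.DataFrame({
            "p_cn": [1.0] * 50, "p_mci": [0.0] * 50, "p_ad": [0.0] * 50,
            "label": ["CN"] * 50,
        })
        tables = reliability_diagrams(preds)
        top = tables["confidence"].iloc[-1]
        assert top["accuracy"] == 1.0
        assert top["count"] == 50

    def test_empty_bin_carries_prior_interval(self):
        preds = pd.DataFrame({
            "p_cn": [1.0] * 10, "p_mci": [0.0] * 10, "p_ad": [0.0] * 10,
            "label": ["CN"] * 10,
        })
        tables = reliability_diagrams(preds)
        empty = tables["class_ad"].iloc[2]  # 0.4-0.6 bin, no mass
        assert empty["count"] == 0
        assert empty["ci_low"] == pytest.approx(0.025, abs=1e-3)
        assert empty["ci_high"] == pytest.approx(0.975, abs=1e-3)

    def test_confidence_table_restricted_above_0_4(self):
        preds = pd.DataFrame({
            "p_cn": [0.4] * 5, "p_mci": [0.35] * 5, "p_ad": [0.25] * 5,
            "label": ["CN"] * 5,
        })
        conf = reliability_diagrams(preds)["confidence"]
        assert (conf["bin_high"] > 0.4).all()

    def test_calibrated_predictor_hits_intervals(self):
        """Labels drawn from the stated probabilities land inside the
        Beta-Binomial intervals around the diagonal in most occupied bins."""
        rng = np.random.default_rng(12345)
        P = rng.dirichlet((1.2, 1.0, 1.1), size=5000)
        labels = np.array([rng.choice(3, p=p) for p in P])
        preds = pd.DataFrame({
            "p_cn": P[:, 0], "p_mci": P[:, 1], "p_ad": P[:, 2],
            "label": pd.Series(labels).map({0: "CN", 1: "MCI", 2: "AD"}),
        })
        tables = reliability_diagrams(preds)
        inside = total = 0
        for name, tab in tables.items():
            if name == "confidence":
                continue
            for _, row in tab.iterrows():
                if row["count"] < 10:
                    continue
                mid_expected = (row["bin_low"] + row["bin_high"]) / 2
                total += 1
                inside += int(row["ci_low"] - 0.05 <= mid_expected <= row["ci_high"] + 0.05)
        assert total >= 8
        assert inside / total >= 0.9


class TestNetBenefit:
    def test_treat_none_identically_zero(self):
        rng = np.random.default_rng(0)
        nb = net_benefit(rng.random(100), rng.random(100) < 0.3)
        assert (nb["nb_treat_none"] == 0.0).all()

    def test_treat_all_crosses_zero_at_prevalence(self):
        labels = np.array([1] * 30 + [0] * 70, dtype=bool)
        prevalence = labels.mean()
        nb = net_benefit(np.random.default_rng(1).random(100), labels,
                         thresholds=np.array([prevalence]))
        assert nb["nb_treat_all"].iloc[0] == pytest.approx(0.0, abs=1e-15)

    def test_perfect_predictor_net_benefit_equals_prevalence(self):
        labels = np.array([1] * 20 + [0] * 80, dtype=bool)
        scores = labels.astype(float)  # P(AD)=1 for cases, 0 for controls
        nb = net_benefit(scores, labels)
        np.testing.assert_allclose(nb["nb_model"], labels.mean(), atol=1e-12)

    def test_degenerate_threshold_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            net_benefit(np.array([0.5]), np.array([True]), thresholds=np.array([1.0]))


class TestConversionErrors:
    def make_tables(self, t50, horizon, converted, event_time):
        preds = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(len(t50))],
            "t50": t50, "horizon": horizon,
        })
        obs = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(len(t50))],
            "converted": converted, "event_time": event_time,
        })
        return preds, obs

    def test_exact_prediction_zero_error(self):
        preds, obs = self.make_tables([4.0], [10.0], [True], [4.0])
        out = conversion_error_analysis(preds, obs)
        assert out["errors"]["error"].iloc[0] == 0.0

    def test_cumulative_curve_reaches_one_within_a_year(self):
        preds, obs = self.make_tables([3.2, 5.9, 7.4], [10.0] * 3, [True] * 3, [3.0, 6.5, 7.0])
        cum = conversion_error_analysis(preds, obs)["cumulative"]
        assert cum["cum_fraction"].iloc[-1] == 1.0
        assert cum["abs_error"].iloc[-1] <= 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_cumulative_curve_matches_sort_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        t50 = rng.uniform(0, 10, n)
        event = rng.uniform(0, 10, n)
        preds, obs = self.make_tables(t50, [10.0] * n, [True] * n, event)
        cum = conversion_error_analysis(preds, obs)["cumulative"]
        errs = sorted(abs(a - b) for a, b in zip(t50, event))
        for i, e in enumerate(errs):
            assert cum["abs_error"].iloc[i] == pytest.approx(e)
            assert cum["cum_fraction"].iloc[i] == pytest.approx((i + 1) / n)

    def test_nonconverter_premature_prediction_is_negative(self):
        preds, obs = self.make_tables([2.0], [10.0], [False], [8.0])
        out = conversion_error_analysis(preds, obs)["errors"]
        assert out["error"].iloc[0] == pytest.approx(-6.0)
        assert not out["converted"].iloc[0]
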
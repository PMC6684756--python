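"""AUC estimators, BCa bootstrap, stratification and concordance screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from xerograd import (
    CohortSimConfig,
    MODEL_MD,
    MODEL_MD_GRADX_PGM,
    bca_interval,
    evaluate_model,
    kendall_concordance,
    lpo_cv_auc,
    mann_whitney_auc,
    simulate_cohort,
    stratify_by_median,
    to_model_table,
)
from tests.conftest import random_cohort


class TestMannWhitneyAuc:
    def test_perfect_ranking(self):
        assert mann_whitney_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_tied_scores_count_half(self):
        # pairs: (2,1)=1, (2,2)=0.5, (3,1)=1, (3,2)=1 -> 3.5/4
        assert mann_whitney_auc([1, 2, 2, 3], [0, 0, 1, 1]) == pytest.approx(0.875)

    def test_matches_sklearn_on_random_scores(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            scores = rng.normal(size=30)
            labels = rng.integers(0, 2, size=30)
            if labels.min() == labels.max():
                continue
            assert mann_whitney_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=25),
        st.integers(1, 2**24),
    )
    def test_direction_flip_identity(self, scores, seed):
        labels = np.random.default_rng(seed).integers(0, 2, len(scores))
        if labels.min() == labels.max():
            return
        hi = mann_whitney_auc(scores, labels, "higher")
        lo = mann_whitney_auc(scores, labels, "lower")
        assert hi + lo == pytest.approx(1.0, abs=1e-12)
        # negation of scores is the same flip
        assert mann_whitney_auc(-np.asarray(scores), labels) == pytest.approx(
            lo, abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_auc([1, 2], [1, 1])


class TestLeavePairOut:
    def test_training_independent_scorer_reduces_to_mann_whitney(self, rng):
        for n in (12, 30, 60):
            df = random_cohort(rng, n=n)
            res = lpo_cv_auc(
                df, MODEL_MD, scorer=lambda train, test: test["md_gy"].to_numpy()
            )
            assert res.auc == pytest.approx(
                mann_whitney_auc(df["md_gy"], df["label"]), abs=1e-12
            )
            assert res.n_pairs == df["label"].sum() * (n - df["label"].sum())

    def test_monotone_separable_cohort_scores_one(self):
        df = pd.DataFrame(
            {"md_gy": np.linspace(0, 30, 14), "label": ([0] * 7 + [1] * 7)}
        )
        res = lpo_cv_auc(df, MODEL_MD, ridge_lambda=0.5)
        assert res.auc == 1.0

    def test_fitted_lpo_close_to_apparent_auc_on_strong_signal(self, demo_cohort):
        # sanity: cross-validated AUC of the full model is meaningfully > 0.5
        res = lpo_cv_auc(demo_cohort, MODEL_MD_GRADX_PGM, ridge_lambda=1.0)
        assert res.auc > 0.6
        assert res.n_skipped == 0

    def test_standardize_false_path_agrees_on_affine_invariance(self, rng):
        # probabilities of an unpenalized logistic fit are invariant to
        # feature centering/scaling, so the two code paths must agree
        df = random_cohort(rng, n=36, n_features=("md",))
        a = lpo_cv_auc(df, MODEL_MD, ridge_lambda=0.0, on_error="skip")
        from xerograd.model import ModelSpec

        b = lpo_cv_auc(
            df, ModelSpec(("md",), standardize=False), ridge_lambda=0.0,
            on_error="skip",
        )
        assert a.auc == pytest.approx(b.auc, abs=1e-9)


class TestBcaBootstrap:
    def test_degenerate_bootstrap_collapses_to_point(self):
        lo, hi = bca_interval(0.7, np.full(100, 0.7), np.full(10, 0.7))
        assert lo == hi == 0.7

    def test_symmetric_case_close_to_percentile_interval(self, rng):
        # sample mean of N(0,1): z0 ~ 0, a ~ 0 -> BCa ~ percentile
        x = rng.normal(size=100)
        theta = x.mean()
        boot = np.array(
            [rng.choice(x, size=100).mean() for _ in range(5000)]
        )
        jack = np.array([np.delete(x, i).mean() for i in range(100)])
        lo, hi = bca_interval(theta, boot, jack)
        plo, phi = np.quantile(boot, [0.025, 0.975])
        assert abs(lo - plo) < 0.03 and abs(hi - phi) < 0.03

    def test_z0_zero_and_a_zero_reduces_to_percentile_exactly(self):
        # construct bootstrap draws with exactly half below theta and a
        # symmetric jackknife -> the BCa endpoints are the raw percentiles
        boot = np.concatenate([np.linspace(0, 0.49, 500), np.linspace(0.51, 1, 500)])
        jack = np.array([-1.0, 1.0, -2.0, 2.0])
        lo, hi = bca_interval(0.5, boot, jack)
        assert lo == pytest.approx(np.quantile(boot, 0.025), abs=1e-9)
        assert hi == pytest.approx(np.quantile(boot, 0.975), abs=1e-9)

    def test_matches_scipy_bca_for_sample_mean(self, rng):
        x = rng.normal(1.0, 2.0, size=80)
        res = stats.bootstrap(
            (x,), np.mean, n_resamples=4000, method="BCa",
            random_state=np.random.default_rng(1), confidence_level=0.95,
        )
        boot_rng = np.random.default_rng(2)
        boot = np.array([boot_rng.choice(x, size=80).mean() for _ in range(4000)])
        jack = np.array([np.delete(x, i).mean() for i in range(80)])
        lo, hi = bca_interval(x.mean(), boot, jack)
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.1)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.1)

    def test_evaluation_result_brackets_point_estimate(self, rng):
        df = random_cohort(rng, n=30, p_pos=0.25)
        df["md_gy"] += 2.0 * df["label"]  # inject signal
        res = evaluate_model(
            df, MODEL_MD, ridge_lambda=1.0, n_bootstrap=60, seed=4
        )
        assert 0 <= res.ci_low <= res.auc <= res.ci_high <= 1
        assert res.n_bootstrap > 0


class TestStratification:
    def test_even_distinct_values_split_equally(self, rng):
        df = random_cohort(rng, n=40)
        res = stratify_by_median(df)
        assert res.n_low == res.n_high == 20

    def test_direction_flip_is_reported(self):
        res_dict = stratify_by_median(
            pd.DataFrame(
                {
                    "md_gy": [1, 2, 3, 4, 10, 20, 30, 40],
                    "gradx_gy_per_mm": [0, 0, 0, 0, 1, 1, 1, 1],
                    "label": [0, 0, 1, 1, 1, 1, 0, 0],
                }
            )
        ).to_dict()
        assert res_dict["auc_high"] == pytest.approx(0.0)
        assert res_dict["auc_high_flipped"] == pytest.approx(1.0)

    def test_opposite_stratum_effects_constructed(self, rng):
        # outcome follows +MD in the low stratum, -MD in the high stratum
        n = 200
        gx = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        md = rng.normal(size=n)
        p = np.where(gx == 0, 1 / (1 + np.exp(-3 * md)), 1 / (1 + np.exp(3 * md)))
        labels = (rng.random(n) < p).astype(int)
        df = pd.DataFrame({"md_gy": md, "gradx_gy_per_mm": gx, "label": labels})
        res = stratify_by_median(df)
        assert res.auc_low > 0.5 > res.auc_high

    def test_single_class_stratum_yields_nan_with_warning(self):
        df = pd.DataFrame(
            {
                "md_gy": [1.0, 2, 3, 4],
                "gradx_gy_per_mm": [0.0, 0, 1, 1],
                "label": [0, 0, 0, 1],
            }
        )
        res = stratify_by_median(df)
        assert np.isnan(res.auc_low) and not np.isnan(res.auc_high)


class TestKendall:
    def test_identity_gives_tau_one(self):
        res = kendall_concordance([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.tau == 1.0 and res.concordance_prob == 1.0

    def test_small_example_by_pair_enumeration(self):
        res = kendall_concordance([1, 2, 3], [2, 1, 3])
        assert res.tau == pytest.approx(1 / 3)

    def test_tau_a_matches_exhaustive_pair_counting(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        s = sum(
            np.sign(x[j] - x[i]) * np.sign(y[j] - y[i])
            for i, j in itertools.combinations(range(40), 2)
        )
        assert kendall_concordance(x, y).tau == pytest.approx(s / (40 * 39 / 2))

    def test_matches_scipy_without_ties(self, rng):
        x, y = rng.normal(size=200), rng.normal(size=200)
        ours = kendall_concordance(x, y).tau
        ref = stats.kendalltau(x, y).statistic
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_concordance_probability_conversion(self):
        assert kendall_concordance([1, 2, 3], [2, 1, 3]).concordance_prob == pytest.approx(
            (1 + 1 / 3) / 2
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kendall_concordance([1, 2], [1, 2, 3])


class TestNullCalibrationAndOrdering:
    def test_mean_model_ordering_over_cohorts(self):
        """Mechanism-generated cohorts: mean LPO AUC must rise with model
        richness (mean-dose only -> +gradient -> +migration)."""
        aucs = []
        for seed in range(200, 220):
            table = to_model_table(
                simulate_cohort(CohortSimConfig(seed=seed)).cohort
            )
            aucs.append(
                [
                    lpo_cv_auc(table, m, ridge_lambda=1.0, on_error="skip").auc
                    for m in (MODEL_MD, MODEL_MD_GRADX_PGM)
                ]
            )
        mean = np.mean(aucs, axis=0)
        assert mean[0] < mean[1]
        assert mean[1] > 0.65  # the full model carries real signal
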
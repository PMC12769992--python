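"""Reader-study statistics: binarization, confusion tallies, pooled
metrics, GEE and ordinal comparisons, and kappa agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dectmd.datasets import counts_for, example_reader_counts
from dectmd.reader_stats import (
    ConfusionCounts,
    binarize,
    cohen_kappa,
    confusion,
    fleiss_kappa,
    gee_compare,
    kappa_z_test,
    metrics,
    ordinal_compare,
    pool,
)
from dectmd.synthetic import CohortConfig, RatingsConfig, generate_ratings, generate_truth


class TestBinarize:
    @pytest.mark.parametrize("rating,positive", [(1, False), (2, False), (3, True), (4, True), (5, True)])
    def test_threshold_at_three(self, rating, positive):
        assert binarize(rating) is positive

    @pytest.mark.parametrize("bad", [0, 6, 2.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            binarize(bad)


def ratings_frame(rows):
    return pd.DataFrame(
        rows, columns=["reader_id", "group", "patient_id", "dataset", "rating", "truth"]
    )


class TestConfusion:
    def test_all_positive_on_all_diseased(self):
        df = ratings_frame(
            [("R1", "expert", f"P{i}", "optimal", 5, "pdac") for i in range(4)]
        )
        c = confusion(df)
        assert (c.tp, c.fp, c.tn, c.fn) == (4, 0, 0, 0)

    def test_counts_match_hand_tally(self, rng):
        n = 60
        ratings = rng.integers(1, 6, n)
        truth = rng.choice(["pdac", "no_pdac"], n)
        df = ratings_frame(
            [("R1", "expert", f"P{i}", "optimal", int(r), t)
             for i, (r, t) in enumerate(zip(ratings, truth))]
        )
        c = confusion(df)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for r, t in zip(ratings, truth):
            pos = r >= 3
            key = ("t" if (pos == (t == "pdac")) else "f") + ("p" if pos else "n")
            tally[key] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (
            tally["tp"], tally["fp"], tally["tn"], tally["fn"]
        )

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            confusion(ratings_frame([]))


class TestMetrics:
    def test_pooled_optimal_dataset_row(self):
        s = metrics(ConfusionCounts(tp=263, fn=5, tn=152, fp=20))
        assert str(s.sensitivity) == "98 (263/268)"
        assert str(s.specificity) == "88 (152/172)"
        assert str(s.ppv) == "93 (263/283)"
        assert str(s.npv) == "97 (152/157)"
        assert str(s.accuracy) == "94 (415/440)"

    def test_pooled_conventional_dataset_row(self):
        s = metrics(ConfusionCounts(tp=264, fn=4, tn=139, fp=33))
        assert str(s.sensitivity) == "99 (264/268)"
        assert str(s.specificity) == "81 (139/172)"
        assert str(s.ppv) == "89 (264/297)"
        assert str(s.npv) == "97 (139/143)"
        assert str(s.accuracy) == "92 (403/440)"

    def test_zero_denominator_flagged_not_thrown(self):
        s = metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        assert not s.sensitivity.defined
        assert s.specificity.percent == 50

    def test_directional_coupling_with_error_counts(self):
        base = ConfusionCounts(tp=50, fn=5, tn=40, fp=10)
        more_fn = ConfusionCounts(tp=45, fn=10, tn=40, fp=10)
        more_fp = ConfusionCounts(tp=50, fn=5, tn=35, fp=15)
        assert metrics(more_fn).sensitivity.proportion < metrics(base).sensitivity.proportion
        assert metrics(more_fn).npv.proportion < metrics(base).npv.proportion
        assert metrics(more_fp).specificity.proportion < metrics(base).specificity.proportion
        assert metrics(more_fp).ppv.proportion < metrics(base).ppv.proportion


class TestPool:
    def test_four_reader_specificity_counts(self):
        per_reader = [
            ConfusionCounts(tn=40, fp=3),
            ConfusionCounts(tn=37, fp=6),
            ConfusionCounts(tn=38, fp=5),
            ConfusionCounts(tn=37, fp=6),
        ]
        pooled = pool(per_reader)
        assert (pooled.tn, pooled.tn + pooled.fp) == (152, 172)

    def test_single_reader_identity_and_doubling(self):
        c = ConfusionCounts(tp=3, fp=1, tn=2, fn=4)
        assert pool([c]) == c
        assert pool([c, c]) == ConfusionCounts(tp=6, fp=2, tn=4, fn=8)

    def test_bundled_example_pools_to_study_totals(self):
        df = example_reader_counts()
        for dataset, spec_counts in (("conventional", (139, 172)), ("optimal", (152, 172))):
            pooled = pool(counts_for(df, dataset))
            assert pooled.total == 440
            assert (pooled.tn, pooled.tn + pooled.fp) == spec_counts


def paired_binary_frame(outcomes_conv, outcomes_opt, truth="no_pdac", reader="R1"):
    """One reader, one row per patient per dataset; outcome=correct-negative
    encoded as rating 1 (correct) / 5 (false positive) for truth-negatives."""
    rows = []
    for i, (c, o) in enumerate(zip(outcomes_conv, outcomes_opt)):
        rows.append((reader, "expert", f"P{i}", "conventional", 1 if c else 5, truth))
        rows.append((reader, "expert", f"P{i}", "optimal", 1 if o else 5, truth))
    return ratings_frame(rows)


class TestGEECompare:
    def test_identical_outcomes_not_calculated(self, rng):
        y = rng.random(40) < 0.8
        res = gee_compare(paired_binary_frame(y, y), "specificity")
        assert res.nc and res.nc_reason == "identical outcomes"

    def test_perfect_metric_not_calculated(self, rng):
        conv = np.ones(30, dtype=bool)
        opt = rng.random(30) < 0.8
        res = gee_compare(paired_binary_frame(conv, opt), "specificity")
        assert res.nc and "100%" in res.nc_reason

    def test_matches_two_proportion_z_test_on_independent_clusters(self, rng):
        # Oracle: with independent single-observation clusters the GEE Wald
        # test must agree with the classic two-proportion z-test.
        n = 2000
        y0 = rng.random(n) < 0.80
        y1 = rng.random(n) < 0.90
        rows = [("R1", "expert", f"C{i}", "conventional", 1 if y else 5, "no_pdac")
                for i, y in enumerate(y0)]
        rows += [("R1", "expert", f"O{i}", "optimal", 1 if y else 5, "no_pdac")
                 for i, y in enumerate(y1)]
        res = gee_compare(ratings_frame(rows), "specificity")
        p0_hat, p1_hat = y0.mean(), y1.mean()
        p_pool = (y0.sum() + y1.sum()) / (2 * n)
        z = (p1_hat - p0_hat) / np.sqrt(p_pool * (1 - p_pool) * 2 / n)
        p_oracle = 2 * stats.norm.sf(abs(z))
        assert not res.nc
        assert np.sign(res.estimate) == np.sign(p1_hat - p0_hat)
        assert res.p_two_sided == pytest.approx(p_oracle, abs=0.02)

    def test_cluster_size_one_independence_equals_logistic_regression(self, rng):
        import statsmodels.api as sm

        n = 300
        y0 = rng.random(n) < 0.7
        y1 = rng.random(n) < 0.85
        rows = [("R1", "expert", f"C{i}", "conventional", 1 if y else 5, "no_pdac")
                for i, y in enumerate(y0)]
        rows += [("R1", "expert", f"O{i}", "optimal", 1 if y else 5, "no_pdac")
                 for i, y in enumerate(y1)]
        res = gee_compare(ratings_frame(rows), "specificity", corstruct="independence")
        outcome = np.r_[y0, y1].astype(float)
        X = sm.add_constant(np.r_[np.zeros(n), np.ones(n)])
        glm = sm.GLM(outcome, X, family=sm.families.Binomial()).fit()
        assert res.estimate == pytest.approx(glm.params[1], abs=1e-6)

    def test_real_difference_detected_on_clustered_data(self):
        cfg = RatingsConfig(spec_conventional=0.70, spec_optimal=0.92, rho=0.3, seed=5)
        truth = generate_truth(CohortConfig(n_pdac=10, n_no_pdac=120))
        ratings = generate_ratings(cfg, truth)
        res = gee_compare(ratings, "specificity")
        assert not res.nc
        assert res.estimate > 0
        assert res.p_two_sided < 0.01


class TestOrdinalCompare:
    @staticmethod
    def latent_ratings(n_patients, shift, seed, truth="pdac"):
        rng = np.random.default_rng(seed)
        cuts = np.array([-1.5, -0.5, 0.5, 1.5])
        rows = []
        for i in range(n_patients):
            u = rng.standard_normal()
            for reader in ("R1", "R2"):
                for dataset, d in (("conventional", 0.0), ("optimal", shift)):
                    s = 0.6 * u + 0.8 * rng.standard_normal() + d
                    rows.append(
                        (reader, "expert", f"P{i}", dataset,
                         int(np.searchsorted(cuts, s)) + 1, truth)
                    )
        return ratings_frame(rows)

    def test_upward_shift_gives_positive_effect_small_p(self):
        df = self.latent_ratings(150, shift=1.0, seed=2)
        res = ordinal_compare(df, "pdac")
        assert not res.nc
        assert res.estimate > 0
        assert res.p_two_sided < 1e-4

    def test_identical_tables_give_null_result(self):
        df = self.latent_ratings(150, shift=0.0, seed=3)
        res = ordinal_compare(df, "pdac")
        assert not res.nc
        assert res.estimate == pytest.approx(0.0, abs=0.25)
        assert res.p_two_sided > 0.05

    def test_recovers_known_latent_shift(self):
        # Probit-scale shift 0.8 of a unit-variance latent corresponds to
        # roughly 0.8 * 1.7 on the logit scale of the proportional-odds fit.
        df = self.latent_ratings(500, shift=0.8, seed=4)
        res = ordinal_compare(df, "pdac")
        assert res.estimate == pytest.approx(0.8 * 1.7, rel=0.25)

    def test_single_category_is_not_calculated(self):
        rows = [("R1", "expert", f"P{i}", ds, 5, "pdac")
                for i in range(10) for ds in ("conventional", "optimal")]
        res = ordinal_compare(ratings_frame(rows), "pdac")
        assert res.nc


class TestKappa:
    def test_perfect_agreement_is_one(self):
        calls = np.array([True, False, True, True, False] * 4)
        res = cohen_kappa(calls, calls.copy())
        assert res.kappa == pytest.approx(1.0)

    def test_independent_raters_near_zero(self, rng):
        # Calls independent by construction at fixed marginals: kappa
        # averages to ~0 over repeated draws.
        kappas = []
        for _ in range(200):
            a = rng.random(60) < 0.6
            b = rng.random(60) < 0.6
            res = cohen_kappa(a, b)
            if not res.undefined:
                kappas.append(res.kappa)
        assert np.mean(kappas) == pytest.approx(0.0, abs=0.02)

    def test_constant_calls_flagged_undefined(self):
        res = cohen_kappa(np.ones(10, bool), np.ones(10, bool))
        assert res.undefined

    def test_point_estimate_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(0, 2, 80)
        b = (a + (rng.random(80) < 0.3)) % 2
        assert cohen_kappa(a, b).kappa == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    def test_fleiss_three_raters_matches_hand_computation(self):
        # 6 items x 3 raters, computed from the definition by hand below.
        calls = np.array(
            [
                [1, 1, 1],
                [1, 1, 0],
                [0, 0, 0],
                [1, 0, 0],
                [0, 0, 1],
                [1, 1, 1],
            ]
        )
        n_items, m = calls.shape
        counts = np.stack([(calls == 0).sum(1), (calls == 1).sum(1)], axis=1)
        p_obs = ((counts * (counts - 1)).sum(1) / (m * (m - 1))).mean()
        p_j = counts.sum(0) / (n_items * m)
        p_exp = (p_j**2).sum()
        expected = (p_obs - p_exp) / (1 - p_exp)
        res = fleiss_kappa(calls)
        assert res.kappa == pytest.approx(expected, abs=1e-12)
        assert res.se > 0

    def test_fleiss_two_raters_consistent_with_two_rater_form(self, rng):
        # On balanced two-rater data Fleiss kappa equals the Scott-pi style
        # two-rater reduction computed directly from the definition.
        a = rng.integers(0, 2, 400)
        b = (a + (rng.random(400) < 0.25)) % 2
        calls = np.stack([a, b], axis=1)
        p_obs = float((a == b).mean())
        p = np.concatenate([a, b]).mean()
        p_exp = p**2 + (1 - p) ** 2
        expected = (p_obs - p_exp) / (1 - p_exp)
        assert fleiss_kappa(calls).kappa == pytest.approx(expected, abs=1e-9)

    def test_kappa_range_bounds(self, rng):
        for _ in range(50):
            a = rng.integers(0, 2, 30)
            b = rng.integers(0, 2, 30)
            res = cohen_kappa(a, b)
            if not res.undefined:
                assert -1.0 - 1e-12 <= res.kappa <= 1.0 + 1e-12

    def test_kappa_z_test_two_sided(self):
        z, p = kappa_z_test(0.52, 0.05, 0.45, 0.04)
        assert z == pytest.approx((0.52 - 0.45) / np.hypot(0.05, 0.04))
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)))
        assert kappa_z_test(0.5, 0.05, 0.5, 0.05)[1] == pytest.approx(1.0)
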
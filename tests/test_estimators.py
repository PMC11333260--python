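"""MR estimator suite: Wald, IVW, Egger, weighted median."""

import numpy as np
import pytest
from scipy import stats

import drugtarget_mr as dm
from drugtarget_mr.estimators import cochran_q_pval

from conftest import make_harmonized


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,by,sy,beta,se",
        [(1.0, 0.5, 0.1, 0.5, 0.1), (-1.0, 0.5, 0.1, -0.5, 0.1), (2.0, 1.0, 0.1, 0.5, 0.05)],
    )
    def test_ratio_arithmetic(self, bx, by, sy, beta, se):
        est = dm.wald_ratio(bx, 0.01, by, sy)
        assert est.beta == pytest.approx(beta)
        assert est.se == pytest.approx(se)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(dm.EstimationError):
            dm.wald_ratio(0.0, 0.01, 0.5, 0.1)


class TestIvw:
    def test_consistent_instruments(self):
        h = make_harmonized([1.0, 2.0], [0.01, 0.01], [0.5, 1.0], [0.1, 0.1])
        est = dm.ivw(h, mode="fixed")
        assert est.beta == pytest.approx(0.5)
        assert est.q == pytest.approx(0.0, abs=1e-20)
        assert est.se == pytest.approx(1 / np.sqrt(500))

    def test_two_snp_longhand_weighted_least_squares(self):
        # weighted regression through the origin computed by hand:
        # w = bx^2/sy^2 = (100, 100); ratios 0.4, 0.6 -> beta 0.5
        # Q = 100*(0.4-0.5)^2 + 100*(0.6-0.5)^2 = 2
        h = make_harmonized([1.0, 1.0], [0.01, 0.01], [0.4, 0.6], [0.1, 0.1])
        est = dm.ivw(h, mode="fixed")
        assert est.beta == pytest.approx(0.5)
        assert est.q == pytest.approx(2.0)
        assert est.q_pval == pytest.approx(stats.chi2.sf(2.0, 1))

    def test_heterogeneity_p_for_ten_instruments(self):
        """Q = 7.352 on 10 instruments refers to chi-square(9): p = 0.601."""
        assert cochran_q_pval(7.352, 9) == pytest.approx(0.601, abs=5e-4)

    def test_reduces_to_wald_with_one_instrument(self):
        h = make_harmonized([2.0], [0.01], [1.0], [0.1])
        est = dm.ivw(h, mode="fixed", min_k=1)
        wald = dm.wald_ratio(2.0, 0.01, 1.0, 0.1)
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(2)
        bx = rng.normal(0.1, 0.02, 6)
        by = 0.3 * bx + rng.normal(0, 0.01, 6)
        h1 = make_harmonized(bx, np.full(6, 0.01), by, np.full(6, 0.05))
        flip = np.array([1, -1, 1, -1, -1, 1.0])
        h2 = make_harmonized(bx * flip, np.full(6, 0.01), by * flip, np.full(6, 0.05))
        assert dm.ivw(h1).beta == pytest.approx(dm.ivw(h2).beta, abs=1e-12)

    def test_random_effects_never_deflates_se(self):
        h = make_harmonized([1.0, 2.0], [0.01, 0.01], [0.5, 1.0], [0.1, 0.1])
        assert dm.ivw(h, mode="multiplicative_random").se >= dm.ivw(h, mode="fixed").se - 1e-15

    def test_binary_outcome_gets_or_fields(self, consistent_set):
        est = dm.ivw(consistent_set, outcome_binary=True)
        assert est.odds_ratio == pytest.approx(np.exp(est.beta))
        assert est.or_low == pytest.approx(np.exp(est.ci_low), rel=1e-12)
        quant = dm.ivw(consistent_set, outcome_binary=False)
        assert quant.odds_ratio is None


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([1.0, 2.0, 3.0])
        h = make_harmonized(bx, np.full(3, 0.01), 0.1 + 0.5 * bx, np.full(3, 0.1))
        est = dm.mr_egger(h)
        assert est.egger_intercept == pytest.approx(0.1, abs=1e-12)
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert est.q == pytest.approx(0.0, abs=1e-18)

    def test_orients_negative_exposure_betas(self):
        bx = np.array([1.0, -2.0, 3.0])
        by = 0.5 * bx  # pure slope, no pleiotropy
        h = make_harmonized(bx, np.full(3, 0.01), by, np.full(3, 0.1))
        est = dm.mr_egger(h)
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_longhand_normal_equations(self):
        rng = np.random.default_rng(7)
        bx = np.abs(rng.normal(0.1, 0.03, 6))
        by = 0.02 + 0.4 * bx + rng.normal(0, 0.01, 6)
        sy = rng.uniform(0.02, 0.08, 6)
        h = make_harmonized(bx, np.full(6, 0.01), by, sy)
        est = dm.mr_egger(h)
        # explicit 2x2 normal equations
        w = 1 / sy**2
        sw, swx, swx2 = w.sum(), (w * bx).sum(), (w * bx**2).sum()
        swy, swxy = (w * by).sum(), (w * bx * by).sum()
        det = sw * swx2 - swx**2
        inter = (swx2 * swy - swx * swxy) / det
        slope = (sw * swxy - swx * swy) / det
        assert est.egger_intercept == pytest.approx(inter, rel=1e-10)
        assert est.beta == pytest.approx(slope, rel=1e-10)

    def test_insufficient_instruments(self):
        h = make_harmonized([1.0, 2.0], [0.01, 0.01], [0.5, 1.0], [0.1, 0.1])
        with pytest.raises(dm.InsufficientInstrumentsError):
            dm.mr_egger(h)

    def test_directional_pleiotropy_detected_majority(self):
        """With a dominant directional pleiotropy component (mean 0.05,
        spread 0.01) the intercept test rejects at 5% in most replicates;
        under balanced pleiotropy the rejection rate stays near nominal.
        The overdispersion-scaled intercept se makes the test conservative,
        so power needs the mean to dominate the spread."""
        rejections = {"directional": 0, "balanced": 0}
        n_rep = 60
        for mode in rejections:
            for rep in range(n_rep):
                truth = dm.SimulationTruth(
                    pleiotropy_mode=mode, pleiotropy_mean=0.05 if mode == "directional" else 0.0,
                    pleiotropy_sd=0.01 if mode == "directional" else 0.02, seed=1000 + rep,
                )
                d = dm.simulate_mediation_gwas(truth, seed=1000 + rep)
                inst = d.exposure_instruments()
                h = dm.harmonize_pair(inst.to_gwas_table(), d.outcome, inst.variant_ids)
                est = dm.mr_egger(h)
                rejections[mode] += est.intercept_pval < 0.05
        assert rejections["directional"] / n_rep > 0.5
        assert 0.0 <= rejections["balanced"] / n_rep <= 0.25


class TestWeightedMedian:
    def test_constant_ratios(self):
        h = make_harmonized([1.0, 2.0, 4.0], [0.01] * 3, [0.3, 0.6, 1.2], [0.1] * 3)
        est = dm.weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.3)

    def test_equal_weights_interpolate_to_middle(self):
        # ratios {0.1, 0.2, 0.3}, equal weights: S = {1/6, 1/2, 5/6}
        h = make_harmonized([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.2, 0.3], [0.1] * 3)
        est = dm.weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_dominant_weight_pulls_to_that_ratio(self):
        # weight ~0.98 on the first ratio
        h = make_harmonized([10.0, 0.2, 0.2], [0.01] * 3, [5.0, 0.02, 0.06], [0.1] * 3)
        est = dm.weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5, abs=0.02)

    def test_seed_required_and_reproducible(self):
        h = make_harmonized([1.0, 1.2, 0.8], [0.01] * 3, [0.5, 0.55, 0.45], [0.1] * 3)
        with pytest.raises(dm.EstimationError):
            dm.weighted_median(h, seed=None)
        a = dm.weighted_median(h, n_boot=100, seed=5)
        b = dm.weighted_median(h, n_boot=100, seed=5)
        assert a.se == b.se


class TestSuite:
    def test_full_suite_on_consistent_data(self):
        """On valid-instrument data every estimator targets the same
        effect: estimates agree within 2 combined se in nearly all seeded
        replicates (individual draws can deviate by chance)."""
        agree = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(800 + rep)
            bx = np.linspace(0.05, 0.3, 10)
            sy = np.full(10, 0.02)
            by = -0.5 * bx + rng.normal(0, sy)
            h = make_harmonized(bx, np.full(10, 0.002), by, sy)
            suite = dm.run_mr_suite(h, outcome_binary=True, seed=rep, n_boot=100, n_sim=200)
            assert [e.method for e in suite] == [
                "ivw_mre", "weighted_median", "egger", "ivw_presso"
            ]
            assert all(e.odds_ratio is not None for e in suite)
            primary = suite[0]
            agree += all(
                abs(est.beta - primary.beta) < 2 * (est.se + primary.se) for est in suite[1:]
            )
        assert agree / n_rep >= 0.85

    def test_quantitative_outcome_has_no_or(self, consistent_set):
        suite = dm.run_mr_suite(consistent_set, outcome_binary=False, seed=1,
                                methods=("ivw", "weighted_median", "egger"), n_boot=50)
        assert all(e.odds_ratio is None for e in suite)

    def test_minimal_k3_returns_three_estimates(self):
        h = make_harmonized([1.0, 1.2, 0.8], [0.01] * 3, [0.5, 0.6, 0.4], [0.1] * 3)
        suite = dm.run_mr_suite(h, outcome_binary=False, seed=2,
                                methods=("ivw", "weighted_median", "egger"), n_boot=50)
        assert len(suite) == 3
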
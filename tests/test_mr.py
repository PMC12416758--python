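"""Two-sample MR estimators and the sex-difference test."""

import numpy as np
import pytest

from shrinkmr import (
    MR_METHODS,
    TwoSampleMR,
    VariantAssoc,
    bh_fdr,
    cml,
    contamination_mixture,
    egger,
    ivw,
    mv_ivw,
    raps,
    run_mr,
    sex_difference_test,
    wald_ratio,
    weighted_median,
)
from shrinkmr.mr import CausalEstimate

from conftest import make_hset


def _va(beta, se, vid="rs1"):
    return VariantAssoc(vid, "A", "G", 0.3, beta, se, 0.5, 1000)


class TestWaldRatio:
    def test_division(self):
        e = wald_ratio(_va(0.1, 0.01), _va(0.02, 0.01))
        assert e.beta == pytest.approx(0.2)

    def test_zero_outcome(self):
        assert wald_ratio(_va(0.1, 0.01), _va(0.0, 0.01)).beta == 0.0

    def test_delta_se(self):
        e = wald_ratio(_va(0.1, 0.01), _va(0.02, 0.01))
        assert e.se == pytest.approx(0.1)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(_va(0.0, 0.01), _va(0.02, 0.01))


def consensus_hset(c=0.2, p=10, seed=0):
    """Instruments whose Wald ratios all equal c exactly, with varying gamma."""
    rng = np.random.default_rng(seed)
    g = rng.uniform(0.05, 0.3, p)
    sg = rng.uniform(0.005, 0.02, p)
    sG = rng.uniform(0.005, 0.02, p)
    return make_hset(g, sg, c * g, sG)


class TestIVW:
    def test_fixed_hand_example(self):
        h = make_hset([0.1, 0.2], [0.01, 0.01], [0.01, 0.04], [0.01, 0.01])
        e = ivw(h, "fixed")
        # weights 100, 400; ratios 0.1, 0.2 -> (100*0.1+400*0.2)/500
        assert e.beta == pytest.approx(0.18, abs=1e-12)
        assert e.se == pytest.approx(1 / np.sqrt(500), rel=1e-12)

    @pytest.mark.parametrize("variant",
                             ["fixed", "penalized", "robust", "penalized_robust"])
    def test_consensus(self, variant):
        e = ivw(consensus_hset(), variant)
        assert e.beta == pytest.approx(0.2, abs=1e-8)

    def test_robust_resists_gross_outlier(self, rng):
        p = 21
        g = rng.uniform(0.1, 0.3, p)
        sG = np.full(p, 0.01)
        G = 0.2 * g + rng.normal(0, 0.002, p)
        G[0] = 5.0 * g[0]  # gross outlier
        h = make_hset(g, np.full(p, 0.005), G, sG)
        fixed = ivw(h, "fixed").beta
        robust = ivw(h, "robust").beta
        assert abs(robust - 0.2) < abs(fixed - 0.2)

    def test_too_few_instruments(self):
        h = make_hset([0.1], [0.01], [0.02], [0.01])
        with pytest.raises(ValueError):
            ivw(h, "fixed")


class TestEgger:
    def test_exact_linear_fit(self, rng):
        g = rng.uniform(0.05, 0.3, 8)
        h = make_hset(g, np.full(8, 0.01), 0.05 + 0.2 * g, np.full(8, 0.01))
        e = egger(h)
        assert e.beta == pytest.approx(0.2, abs=1e-9)
        assert e.diagnostics["egger_intercept"] == pytest.approx(0.05, abs=1e-9)

    def test_zero_intercept_exact_data_matches_ivw(self, rng):
        e = egger(consensus_hset(seed=3))
        f = ivw(consensus_hset(seed=3), "fixed")
        assert e.beta == pytest.approx(f.beta, abs=1e-9)

    def test_reorientation_invariance(self, rng):
        g = rng.uniform(0.05, 0.3, 8)
        G = 0.05 + 0.2 * g + rng.normal(0, 0.01, 8)
        h1 = make_hset(g, np.full(8, 0.01), G, np.full(8, 0.01))
        g2, G2 = g.copy(), G.copy()
        g2[2:4] *= -1
        G2[2:4] *= -1
        h2 = make_hset(g2, np.full(8, 0.01), G2, np.full(8, 0.01))
        a, b = egger(h1), egger(h2)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)

    def test_requires_three(self):
        with pytest.raises(ValueError):
            egger(make_hset([0.1, 0.2], [0.01, 0.01], [0.01, 0.02], [0.01, 0.01]))


def oracle_weighted_median(ratios, weights):
    """Brute-force weighted median by cumulative-weight interpolation."""
    order = np.argsort(ratios)
    r = np.asarray(ratios)[order]
    w = np.asarray(weights)[order]
    w = w / w.sum()
    cum = np.cumsum(w) - w / 2
    if cum[0] >= 0.5:
        return r[0]
    if cum[-1] < 0.5:
        return r[-1]
    for k in range(1, len(r)):
        if cum[k] >= 0.5:
            return r[k - 1] + (r[k] - r[k - 1]) * (0.5 - cum[k - 1]) / (
                cum[k] - cum[k - 1]
            )


class TestWeightedMedian:
    def test_plain_median_with_equal_weights(self):
        # equal-precision ratios 0.1/0.2/0.3 -> plain median 0.2
        g = np.array([0.1, 0.1, 0.1])
        G = g * np.array([0.1, 0.2, 0.3])
        h = make_hset(g, [1e-12] * 3, G, [0.01] * 3)
        assert weighted_median(h).beta == pytest.approx(0.2, abs=1e-9)

    def test_majority_valid(self):
        # 3 precise IVs at ratio 0.2 carry >60% of weight; 2 noisy ones at 5.0
        g = np.full(5, 0.2)
        G = np.array([0.04, 0.04, 0.04, 1.0, 1.0])
        sG = np.array([0.01, 0.01, 0.01, 0.2, 0.2])
        h = make_hset(g, [0.001] * 5, G, sG)
        assert weighted_median(h).beta == pytest.approx(0.2, abs=1e-6)

    def test_matches_bruteforce_oracle(self, rng):
        g = rng.uniform(0.05, 0.3, 9)
        sg = rng.uniform(0.002, 0.01, 9)
        G = rng.normal(0.2 * g, 0.01)
        sG = rng.uniform(0.005, 0.02, 9)
        h = make_hset(g, sg, G, sG)
        est = weighted_median(h)
        ratios = G / g
        var = sG**2 / g**2
        assert est.beta == pytest.approx(
            oracle_weighted_median(ratios, 1 / var), abs=1e-12
        )

    def test_bootstrap_se_reproducible(self, rng):
        h = make_hset(rng.uniform(0.1, 0.3, 6), [0.01] * 6,
                      rng.normal(0.02, 0.01, 6), [0.01] * 6)
        a = weighted_median(h, seed=7)
        b = weighted_median(h, seed=7)
        assert a.se == b.se


class TestConMix:
    def test_tight_cluster_recovered(self):
        h = consensus_hset(c=0.2, p=8)
        e = contamination_mixture(h)
        assert abs(e.beta - 0.2) <= e.diagnostics["grid_step"]
        assert e.diagnostics["n_invalid"] == 0
        assert not e.diagnostics["multimodal"]

    def test_two_clusters_flagged_multimodal(self, rng):
        g = np.full(10, 0.2)
        ratios = np.r_[np.full(5, 0.2), np.full(5, 1.0)]
        G = ratios * g
        h = make_hset(g, [0.001] * 10, G, [0.004] * 10)
        e = contamination_mixture(h, psi=0.05)
        near_mode = min(abs(e.beta - 0.2), abs(e.beta - 1.0))
        assert near_mode <= 2 * e.diagnostics["grid_step"]
        assert len(e.diagnostics["likelihood_ci_components"]) >= 1

    def test_grid_oracle_agreement(self, rng):
        """Independent coarse grid search lands on the same optimum."""
        from scipy import stats

        g = rng.uniform(0.1, 0.3, 12)
        G = 0.3 * g + rng.normal(0, 0.005, 12)
        sG = np.full(12, 0.01)
        h = make_hset(g, np.full(12, 0.001), G, sG)
        e = contamination_mixture(h)
        ratios, se_r = G / g, sG / g
        psi = e.diagnostics["psi"]

        def ll(b):
            lv = stats.norm.logpdf(ratios, b, se_r)
            li = stats.norm.logpdf(ratios, 0, np.sqrt(psi**2 + se_r**2))
            return np.maximum(lv, li).sum()

        grid = np.linspace(ratios.min() - 0.2, ratios.max() + 0.2, 4001)
        oracle = grid[np.argmax([ll(b) for b in grid])]
        assert e.beta == pytest.approx(oracle, abs=2 * e.diagnostics["grid_step"]
                                       + (grid[1] - grid[0]))


class TestCML:
    def test_k0_matches_profile_likelihood_oracle(self, rng):
        g = rng.uniform(0.1, 0.3, 5)
        sg = np.full(5, 0.01)
        G = 0.2 * g + rng.normal(0, 0.01, 5)
        sG = np.full(5, 0.01)
        h = make_hset(g, sg, G, sG)
        e = cml(h, k_grid=[0])
        # independent numeric oracle: dense grid + golden refinement
        def nll(b):
            return np.sum((G - b * g) ** 2 / (sG**2 + b**2 * sg**2))

        grid = np.linspace(-1, 1, 20001)
        b0 = grid[np.argmin([nll(b) for b in grid])]
        from scipy.optimize import minimize_scalar

        oracle = minimize_scalar(nll, bracket=(b0 - 1e-3, b0, b0 + 1e-3)).x
        assert e.beta == pytest.approx(oracle, abs=1e-6)

    def test_detects_two_pleiotropic_ivs(self):
        """With 2 of 10 IVs strongly pleiotropic, BIC selects K=2 in >=90%
        of replicates."""
        hits = 0
        n_rep = 200
        rng = np.random.default_rng(7)
        for _ in range(n_rep):
            g = rng.uniform(0.1, 0.3, 10)
            sg = np.full(10, 0.005)
            sG = np.full(10, 0.01)
            alpha = np.zeros(10)
            alpha[:2] = 0.15
            G = 0.1 * g + alpha + rng.normal(0, sG)
            gh = g + rng.normal(0, sg)
            h = make_hset(gh, sg, G, sG, n_exp=50_000, n_out=50_000)
            e = cml(h)
            hits += e.diagnostics["K_selected"] == 2
        assert hits / n_rep >= 0.9

    def test_small_exposure_error_limit_matches_ivw(self, rng):
        g = rng.uniform(0.1, 0.3, 8)
        G = 0.2 * g + rng.normal(0, 0.01, 8)
        sG = np.full(8, 0.01)
        h = make_hset(g, np.full(8, 1e-8), G, sG)
        e = cml(h, k_grid=[0])
        f = ivw(h, "fixed")
        assert e.beta == pytest.approx(f.beta, abs=1e-6)


class TestRAPS:
    def test_small_exposure_error_l2_limit_matches_ivw(self, rng):
        g = rng.uniform(0.1, 0.3, 10)
        G = 0.2 * g + rng.normal(0, 0.01, 10)
        h = make_hset(g, np.full(10, 1e-9), G, np.full(10, 0.01))
        e = raps(h, overdispersion=False, loss="l2")
        f = ivw(h, "fixed")
        assert e.beta == pytest.approx(f.beta, abs=1e-8)
        assert e.se == pytest.approx(f.se, rel=1e-3)

    def test_consensus_with_tiny_noise(self, rng):
        g = rng.uniform(0.1, 0.3, 10)
        G = 0.25 * g + rng.normal(0, 1e-9, 10)
        h = make_hset(g, np.full(10, 0.005), G, np.full(10, 0.01))
        e = raps(h)
        assert e.beta == pytest.approx(0.25, abs=1e-6)

    def test_loss_options(self, rng):
        h = consensus_hset(p=12, seed=5)
        for loss in ("l2", "huber", "tukey"):
            e = raps(h, loss=loss)
            assert e.beta == pytest.approx(0.2, abs=1e-6)

    def test_overdispersion_estimated_nonnegative(self, rng):
        g = rng.uniform(0.1, 0.3, 30)
        G = 0.2 * g + rng.normal(0, 0.05, 30)  # extra spread beyond stated SEs
        h = make_hset(g, np.full(30, 0.005), G, np.full(30, 0.01))
        e = raps(h, overdispersion=True, loss="l2")
        assert e.diagnostics["tau2"] > 0


class TestMVIVW:
    def test_null_second_exposure_reduces_to_univariable(self, rng):
        g1 = rng.uniform(0.1, 0.3, 10)
        g2 = np.zeros(10)
        G = 0.2 * g1 + rng.normal(0, 0.01, 10)
        sG = np.full(10, 0.01)
        h1 = make_hset(g1, np.full(10, 0.005), G, sG)
        h2 = make_hset(g2, np.full(10, 0.005), G, sG)
        ests = mv_ivw([h1, h2])
        uni = ivw(h1, "fixed")
        assert ests[0].beta == pytest.approx(uni.beta, abs=1e-9)
        assert ests[1].beta == 0.0 and np.isinf(ests[1].se)

    def test_exact_linear_system_recovered(self, rng):
        g1 = rng.uniform(0.1, 0.3, 12)
        g2 = rng.uniform(0.1, 0.3, 12)
        G = 0.1 * g1 + 0.3 * g2
        sG = np.full(12, 0.01)
        h1 = make_hset(g1, np.full(12, 0.005), G, sG)
        h2 = make_hset(g2, np.full(12, 0.005), G, sG)
        ests = mv_ivw([h1, h2])
        assert ests[0].beta == pytest.approx(0.1, abs=1e-9)
        assert ests[1].beta == pytest.approx(0.3, abs=1e-9)

    def test_adjusting_for_confounding_exposure_helps(self, rng):
        """When the outcome loads on a second, correlated exposure, MVMR is
        closer to the truth than univariable IVW."""
        errs_uni, errs_mv = [], []
        for rep in range(30):
            g1 = rng.uniform(0.1, 0.3, 20)
            g2 = 0.8 * g1 + rng.uniform(0.0, 0.1, 20)
            sG = np.full(20, 0.01)
            G = 0.1 * g1 + 0.3 * g2 + rng.normal(0, 0.01, 20)
            h1 = make_hset(g1, np.full(20, 0.005), G, sG)
            h2 = make_hset(g2, np.full(20, 0.005), G, sG)
            errs_uni.append(abs(ivw(h1, "fixed").beta - 0.1))
            errs_mv.append(abs(mv_ivw([h1, h2])[0].beta - 0.1))
        assert np.mean(errs_mv) < np.mean(errs_uni)

    def test_rank_deficiency_rejected(self, rng):
        g1 = rng.uniform(0.1, 0.3, 10)
        G = 0.2 * g1
        sG = np.full(10, 0.01)
        h1 = make_hset(g1, np.full(10, 0.005), G, sG)
        h2 = make_hset(2 * g1, np.full(10, 0.005), G, sG)
        with pytest.raises(ValueError, match="rank"):
            mv_ivw([h1, h2])


class TestSexDifference:
    def test_equal_estimates_give_p_one(self):
        a = CausalEstimate(0.2, 0.05, "raps", 10)
        r = sex_difference_test(a, CausalEstimate(0.2, 0.08, "raps", 10))
        assert r.statistic == 0.0
        assert r.pvalue == 1.0
        assert r.se_diff == pytest.approx(np.sqrt(0.05**2 + 0.08**2), abs=1e-12)

    def test_published_style_ci_recovery(self):
        """diff -0.275 with 95% CI (-0.521, -0.029): p ~ 0.028."""
        se = (0.521 - 0.029) / 2 / 1.96
        f = CausalEstimate(-0.275, se / np.sqrt(2), "raps", 10)
        m = CausalEstimate(0.0, se / np.sqrt(2), "raps", 10)
        r = sex_difference_test(f, m)
        assert r.diff == pytest.approx(-0.275)
        assert r.pvalue == pytest.approx(0.028, abs=0.001)

    def test_bh_on_constant_pvalues(self):
        assert np.allclose(bh_fdr([0.05] * 7), 0.05)

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 25)
        ours = bh_fdr(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)


class TestDispatchAndInvariants:
    def test_run_mr_dispatch(self):
        h = consensus_hset()
        a = run_mr(h, "ivw_fixed")
        b = ivw(h, "fixed")
        assert a.beta == b.beta
        assert a.diagnostics["exposure_calibration"] == "raw"

    def test_unknown_method_lists_valid(self):
        with pytest.raises(ValueError, match="ivw_fixed"):
            run_mr(consensus_hset(), "mr_foo")

    def test_model_interface(self):
        h = consensus_hset()
        model = TwoSampleMR(h, calibration="apm")
        est = model.fit("ivw_fixed")
        assert est.diagnostics["exposure_calibration"] == "apm"
        table = model.fit_all(["ivw_fixed", "egger"])
        assert len(table) == 2

    @pytest.mark.parametrize("method", sorted(MR_METHODS))
    def test_consensus_across_methods(self, method):
        h = consensus_hset(c=0.2, p=10)
        e = run_mr(h, method)
        tol = 2 * e.diagnostics["grid_step"] if method == "conmix" else 1e-6
        assert e.beta == pytest.approx(0.2, abs=tol)

    @pytest.mark.parametrize("method", sorted(MR_METHODS))
    def test_scale_equivariance(self, method, rng):
        g = rng.uniform(0.1, 0.3, 10)
        G = 0.2 * g + rng.normal(0, 0.01, 10)
        sG = np.full(10, 0.01)
        h1 = make_hset(g, np.full(10, 0.005), G, sG)
        c = 2.5
        h2 = make_hset(g, np.full(10, 0.005), c * G, c * sG)
        a = run_mr(h1, method)
        b = run_mr(h2, method)
        tol = 3 * b.diagnostics["grid_step"] if method == "conmix" else 1e-5
        assert b.beta == pytest.approx(c * a.beta, abs=tol)
        se_tol = 0.1 * c * a.se if method == "conmix" else 1e-4 * c * a.se
        assert b.se == pytest.approx(c * a.se, abs=max(se_tol, 1e-10))

    @pytest.mark.parametrize("method", sorted(MR_METHODS))
    def test_allele_orientation_invariance(self, method, rng):
        g = rng.uniform(0.1, 0.3, 10)
        G = 0.2 * g + rng.normal(0, 0.01, 10)
        sG = np.full(10, 0.01)
        h1 = make_hset(g, np.full(10, 0.005), G, sG)
        g2, G2 = g.copy(), G.copy()
        flip = [1, 4, 7]
        g2[flip] *= -1
        G2[flip] *= -1
        h2 = make_hset(g2, np.full(10, 0.005), G2, sG)
        a = run_mr(h1, method)
        b = run_mr(h2, method)
        assert b.beta == pytest.approx(a.beta, rel=1e-9, abs=1e-12)
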
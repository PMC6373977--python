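import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from mrphescan import mr
from mrphescan.synthetic import simulate_summary_stats


def _stats(bx, by, sy, sx=None):
    n = len(bx)
    return pd.DataFrame({
        "beta_exposure": bx, "se_exposure": sx if sx is not None else [0.0] * n,
        "beta_outcome": by, "se_outcome": sy,
    })


class TestRatioEstimates:
    def test_delta_method_arithmetic(self):
        st = _stats([0.1], [0.02], [0.01])
        r = mr.ratio_estimates(st)
        assert r["ratio"].iloc[0] == pytest.approx(0.2)
        assert r["se_ratio"].iloc[0] == pytest.approx(0.1)

    def test_zero_outcome_beta_gives_zero_ratio(self):
        r = mr.ratio_estimates(_stats([0.1], [0.0], [0.01]))
        assert r["ratio"].iloc[0] == 0.0

    def test_scale_invariance(self):
        a = mr.ratio_estimates(_stats([0.1, 0.2], [0.02, 0.05], [0.01, 0.01]))
        b = mr.ratio_estimates(_stats([0.2, 0.4], [0.04, 0.10], [0.01, 0.01]))
        assert np.allclose(a["ratio"], b["ratio"])

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError):
            mr.ratio_estimates(_stats([0.0], [0.01], [0.01]))


class TestIvw:
    def test_shared_exact_ratio_recovered_with_zero_q(self):
        bx = np.array([0.05, 0.1, 0.2])
        st = _stats(bx, 0.3 * bx, [0.01, 0.02, 0.01])
        est = mr.ivw(st)
        assert est.beta == pytest.approx(0.3)
        assert est.diagnostics["Q"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_weighted_normal_equations(self, hand_sumstats):
        bx = hand_sumstats["beta_exposure"].to_numpy()
        by = hand_sumstats["beta_outcome"].to_numpy()
        w = 1 / hand_sumstats["se_outcome"].to_numpy() ** 2
        beta_hand = np.sum(w * bx * by) / np.sum(w * bx * bx)
        se_hand = np.sqrt(1 / np.sum(w * bx * bx))
        est = mr.ivw(hand_sumstats, random_effects=False)
        assert est.beta == pytest.approx(beta_hand)
        assert est.se == pytest.approx(se_hand)

    def test_unbiased_without_pleiotropy(self):
        betas = [mr.ivw(simulate_summary_stats(40, 0.1, seed=s, se_outcome=0.01)).beta
                 for s in range(200)]
        mc_se = np.std(betas, ddof=1) / np.sqrt(200)
        assert abs(np.mean(betas) - 0.1) < 3 * mc_se

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            mr.ivw(_stats([0.1], [0.01], [0.01]))


class TestEgger:
    def test_exact_line_through_origin(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        st = _stats(bx, 0.4 * bx, [0.01] * 4)
        est = mr.egger(st)
        assert est.beta == pytest.approx(0.4)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_with_intercept(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        st = _stats(bx, 0.02 + 0.4 * bx, [0.01, 0.02, 0.01, 0.03])
        est = mr.egger(st)
        assert est.beta == pytest.approx(0.4)
        assert est.intercept == pytest.approx(0.02)

    def test_matches_statsmodels_wls(self, hand_sumstats):
        w = 1 / hand_sumstats["se_outcome"] ** 2
        X = sm.add_constant(hand_sumstats["beta_exposure"])
        fit = sm.WLS(hand_sumstats["beta_outcome"], X, weights=w).fit()
        est = mr.egger(hand_sumstats)
        assert est.beta == pytest.approx(fit.params["beta_exposure"])
        assert est.intercept == pytest.approx(fit.params["const"])

    def test_negative_exposure_betas_oriented_positive(self, hand_sumstats):
        flipped = hand_sumstats.copy()
        flipped.loc[0, ["beta_exposure", "beta_outcome"]] *= -1
        assert mr.egger(flipped).beta == pytest.approx(mr.egger(hand_sumstats).beta)

    def test_balanced_pleiotropy_intercept_covers_zero(self, rng):
        cover = 0
        reps = 100
        for s in range(reps):
            alpha = np.random.default_rng(10_000 + s).normal(0, 0.002, 50)
            st = simulate_summary_stats(50, 0.1, seed=s, se_outcome=0.005,
                                        pleiotropy=alpha)
            e = mr.egger(st)
            if abs(e.intercept) < 1.96 * e.intercept_se:
                cover += 1
        assert cover >= 0.9 * reps


class TestI2gx:
    def test_identical_exposure_betas_clamp_to_zero(self):
        st = _stats([0.1, 0.1, 0.1], [0.02, 0.03, 0.01], [0.01] * 3, sx=[0.01] * 3)
        assert mr.i2gx(st) == 0.0

    def test_error_free_limit_is_one(self):
        st = _stats([0.05, 0.1, 0.2], [0.01, 0.02, 0.04], [0.01] * 3,
                    sx=[1e-9, 1e-9, 1e-9])
        assert mr.i2gx(st) > 0.999

    def test_hand_computed_q_formula(self):
        bx = np.array([0.05, 0.08, 0.12, 0.2])
        sx = np.array([0.01, 0.02, 0.015, 0.03])
        st = _stats(bx, bx, [0.01] * 4, sx=sx)
        w = 1 / sx**2
        mu = np.sum(w * bx) / np.sum(w)
        q = np.sum(w * (bx - mu) ** 2)
        expected = max(0.0, (q - 3) / q)
        assert mr.i2gx(st) == pytest.approx(expected)


class TestSimex:
    def test_extrapolant_exact_on_known_quadratic(self):
        lam = [0.0, 0.5, 1.0, 1.5, 2.0]
        quad = [2 + 3 * l - 0.5 * l**2 for l in lam]
        value = mr.simex_extrapolate(lam, quad, "quadratic")
        assert value == pytest.approx(2 + 3 * (-1) - 0.5 * 1, rel=1e-9)

    def test_degenerates_to_egger_without_exposure_error(self, hand_sumstats):
        st = hand_sumstats.copy()
        st["se_exposure"] = 1e-12
        cfg = mr.SimexConfig(reps_per_lambda=5, seed=1)
        assert mr.egger_simex(st, cfg).beta == pytest.approx(mr.egger(st).beta, abs=1e-6)

    def test_seed_reproducible(self, hand_sumstats):
        cfg = mr.SimexConfig(reps_per_lambda=20, seed=7)
        a = mr.egger_simex(hand_sumstats, cfg)
        b = mr.egger_simex(hand_sumstats, cfg)
        assert a.beta == b.beta

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            mr.SimexConfig(lambda_grid=(0.5, 1.0))
        with pytest.raises(ValueError):
            mr.egger_simex(_stats([0.1] * 3, [0.01] * 3, [0.01] * 3),
                           mr.SimexConfig(reps_per_lambda=1))


class TestWeightedMedian:
    def test_equal_weight_median(self):
        st = _stats([0.1, 0.1, 0.1], [0.1 * 1, 0.1 * 2, 0.1 * 9], [0.01] * 3)
        est = mr.weighted_median(st, bootstrap_reps=50, seed=0)
        assert est.beta == pytest.approx(2.0)

    def test_interpolation_between_order_statistics(self):
        # ratios 1,2,3,4 with weights 0.1,0.2,0.3,0.4 (already normalized)
        bx = np.array([1.0, 1.0, 1.0, 1.0])
        by = np.array([1.0, 2.0, 3.0, 4.0])
        sy = 1 / np.sqrt(np.array([0.1, 0.2, 0.3, 0.4]))
        st = _stats(bx, by, sy)
        cum = np.array([0.05, 0.2, 0.45, 0.8])  # cumsum - w/2
        expected = np.interp(0.5, cum, by)
        est = mr.weighted_median(st, bootstrap_reps=50, seed=0)
        assert est.beta == pytest.approx(expected)

    def test_breakdown_behaviour_at_fifty_percent_invalid(self):
        """Consistent with 40% invalid weight, biased when 60% is invalid
        and directional (the IVW is biased in both)."""
        n_snps, theta = 50, 0.1
        for frac, should_recover in [(0.4, True), (0.6, False)]:
            n_bad = int(frac * n_snps)
            alpha = np.zeros(n_snps)
            alpha[:n_bad] = 0.03  # directional pleiotropy, all one way
            est, ivw_est = [], []
            for s in range(40):
                # equal exposure betas make the invalid weight mass exact
                st = simulate_summary_stats(
                    n_snps, theta, seed=s, se_outcome=0.001, pleiotropy=alpha,
                    beta_exposure_range=(0.05, 0.0500001),
                )
                est.append(mr.weighted_median(st, bootstrap_reps=10, seed=s).beta)
                ivw_est.append(mr.ivw(st).beta)
            err = abs(np.mean(est) - theta)
            assert (err < 0.05) == should_recover
            assert abs(np.mean(ivw_est) - theta) > 0.1  # IVW biased either way


class TestModeBasedEstimate:
    def test_identical_ratios_give_that_value(self):
        bx = np.array([0.1, 0.2, 0.4])
        st = _stats(bx, 0.25 * bx, [0.01] * 3)
        for phi in (0.5, 0.75, 1.0):
            est = mr.mode_based_estimate(st, phi=phi, bootstrap_reps=10, seed=0)
            assert est.beta == pytest.approx(0.25, abs=1e-3)

    def test_majority_peak_wins_in_bimodal_set(self):
        bx = np.ones(5)
        by = np.array([0.0, 0.0, 0.0, 0.5, 0.5])
        st = _stats(bx, by, [0.05] * 5)
        est = mr.mode_based_estimate(st, phi=0.25, bootstrap_reps=10, seed=0)
        assert abs(est.beta - 0.0) < 0.05

    def test_weighted_mode_pulled_to_dominant_weight(self):
        bx = np.ones(4)
        by = np.array([0.0, 0.0, 0.5, 0.5])
        sy = np.array([0.5, 0.5, 0.5, 1e-4])  # one near-infinite weight
        st = _stats(bx, by, sy)
        est = mr.mode_based_estimate(st, phi=0.5, weighted=True,
                                     bootstrap_reps=10, seed=0)
        assert abs(est.beta - 0.5) < 0.05

    def test_nonpositive_phi_rejected(self, hand_sumstats):
        with pytest.raises(ValueError):
            mr.mode_based_estimate(hand_sumstats, phi=0.0)

    def test_density_curves_cover_requested_phis(self, hand_sumstats):
        curves = mr.mbe_density_curves(hand_sumstats, phis=(0.5, 0.75, 1.0))
        assert sorted(curves["phi"].unique()) == [0.5, 0.75, 1.0]
        assert (curves["density"] >= 0).all()


class TestInstrumentHeterogeneity:
    def test_identical_estimates_give_p_one(self):
        a = mr.MREstimate("a", 0.2, 0.05, 10)
        assert mr.instrument_heterogeneity(a, a) == pytest.approx(1.0)

    def test_z_at_1_96_gives_p_005(self):
        se = 0.05
        gap = 1.96 * np.sqrt(2 * se**2)
        a = mr.MREstimate("a", 0.1 + gap, se, 10)
        b = mr.MREstimate("b", 0.1, se, 10)
        assert mr.instrument_heterogeneity(a, b) == pytest.approx(0.05, rel=1e-3)

    def test_cdf_oracle(self):
        a = mr.MREstimate("a", 0.2, 0.05, 10)
        b = mr.MREstimate("b", 0.05, 0.05, 10)
        z = 0.15 / np.sqrt(2 * 0.05**2)
        assert mr.instrument_heterogeneity(a, b) == pytest.approx(2 * stats.norm.sf(z))

    def test_zero_se_rejected(self):
        a = mr.MREstimate("a", 0.2, 0.0, 10)
        with pytest.raises(ValueError):
            mr.instrument_heterogeneity(a, a)


def test_suite_agreement_without_pleiotropy():
    """IVW, Egger, weighted median and MBE agree when every SNP is valid."""
    st = simulate_summary_stats(97, 0.1, seed=12, se_exposure=0.001, se_outcome=0.004)
    table = mr.run_suite(st, bootstrap_reps=100, seed=0,
                         simex_config=mr.SimexConfig(reps_per_lambda=50, seed=0))
    assert set(table["method"]) == {"ivw", "egger", "egger-simex",
                                    "weighted-median", "simple-mbe", "weighted-mbe"}
    betas = table.set_index("method")["beta"]
    assert np.all(np.abs(betas - 0.1) < 0.05)
    i2 = table.set_index("method").loc["egger", "i2gx"]
    assert 0 <= i2 <= 1
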
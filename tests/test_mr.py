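import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.base import clone

from targetmr.exceptions import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from targetmr.mr import (
    IVW,
    Egger,
    MRPresso,
    WaldRatio,
    WeightedMedian,
    WeightedMode,
    cochran_q,
    egger,
    ivw,
    mr_presso,
    steiger,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from targetmr.simulate import (
    SimulationConfig,
    inject_outlier,
    simulate_instrument_set,
)

from conftest import make_hset


def _random_hset(seed, k=30):
    pair = simulate_instrument_set(
        SimulationConfig(n_snps=k, seed=seed), flip_alleles=False
    )
    return pair.to_harmonized()


class TestWaldRatio:
    def test_arithmetic(self):
        h = make_hset([0.5], [0.01], [0.25], [0.05])
        res = wald_ratio(h)
        assert res.estimate == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_zero_outcome_beta(self):
        res = wald_ratio(make_hset([0.5], [0.01], [0.0], [0.05]))
        assert res.estimate == 0.0

    def test_zero_exposure_beta_errors(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(make_hset([0.0], [0.01], [0.1], [0.05]))

    def test_multi_snp_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            wald_ratio(make_hset([0.5, 0.5], [0.01, 0.01], [0.1, 0.1],
                                 [0.05, 0.05]))

    def test_second_order_se_matches_sampling(self, rng):
        # z_exp = 20: compare the delta-method SE with the Monte-Carlo SD
        # of the actual ratio distribution
        bx, sx, by, sy = 1.0, 0.05, 0.5, 0.05
        res = wald_ratio(
            make_hset([bx], [sx], [by], [sy]), second_order=True
        )
        draws = rng.normal(by, sy, 500_000) / rng.normal(bx, sx, 500_000)
        assert res.se == pytest.approx(draws.std(), rel=0.05)


class TestIVW:
    def test_closed_form_example(self, toy_hset):
        res, sens = ivw(toy_hset)
        assert res.estimate == pytest.approx(0.5)
        assert sens.q == pytest.approx(2.0)
        # fixed se 1/sqrt(200); RE scale sqrt(Q/1) doubles it to 0.1
        assert res.se == pytest.approx(0.1)
        est = IVW().fit(toy_hset)
        assert est.se_fixed_ == pytest.approx(1 / np.sqrt(200))

    def test_single_snp_equals_wald(self):
        h = make_hset([0.37], [0.012], [0.21], [0.043])
        res_i, _ = ivw(h)
        res_w = wald_ratio(h)
        assert res_i.estimate == pytest.approx(res_w.estimate, abs=1e-12)
        assert res_i.se == pytest.approx(res_w.se, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_wls_normal_equations(self, seed):
        h = _random_hset(seed)
        res, _ = ivw(h, random_effects=False)
        fit = sm.WLS(
            h.df["beta_out"], h.df["beta_exp"],
            weights=1.0 / h.df["se_out"] ** 2,
        ).fit()
        assert abs(res.estimate - fit.params.iloc[0]) < 1e-10

    def test_degenerate_all_zero_exposure(self):
        with pytest.raises(DegenerateInstrumentError):
            ivw(make_hset([0.0, 0.0], [0.01, 0.01], [0.1, 0.1], [0.05, 0.05]))

    def test_random_effects_never_shrinks_se(self):
        for seed in range(5):
            h = _random_hset(seed, k=10)
            re, _ = ivw(h, random_effects=True)
            fe, _ = ivw(h, random_effects=False)
            assert re.se >= fe.se - 1e-15


class TestEgger:
    def test_too_few_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_hset([0.1, 0.2], [0.01, 0.01], [0.1, 0.1], [0.05, 0.05]))

    def test_degenerate_equal_betas_i2gx_zero(self):
        h = make_hset([0.2, 0.2, 0.2], [0.01, 0.01, 0.01],
                      [0.1, 0.12, 0.08], [0.05, 0.05, 0.05])
        _, sens = egger(h)
        assert sens.i2_gx == 0.0

    def test_zero_intercept_mode_reproduces_fixed_ivw(self):
        for seed in range(3):
            h = _random_hset(seed)
            est = Egger(with_intercept=False).fit(h)
            res, _ = ivw(h, random_effects=False)
            assert abs(est.estimate_ - res.estimate) < 1e-10

    def test_intercept_near_zero_without_pleiotropy(self):
        h = _random_hset(4, k=50)
        _, sens = egger(h)
        assert abs(sens.egger_intercept) < 5 * sens.egger_intercept_se


class TestOrientationInvariance:
    @pytest.mark.parametrize(
        "fit_fn",
        [
            lambda h: ivw(h)[0].estimate,
            lambda h: egger(h)[0].estimate,
            lambda h: weighted_median(h, n_boot=50, seed=1).estimate,
            lambda h: weighted_mode(h, n_boot=20, seed=1).estimate,
        ],
    )
    def test_per_snp_sign_flips_do_not_change_estimates(self, fit_fn, rng):
        h = _random_hset(9, k=20)
        flipped = h.subset(np.ones(h.k, dtype=bool))
        signs = np.where(rng.random(h.k) < 0.5, -1.0, 1.0)
        flipped.df["beta_exp"] *= signs
        flipped.df["beta_out"] *= signs
        assert fit_fn(h) == pytest.approx(fit_fn(flipped), abs=1e-10)


class TestWeightedMedian:
    def test_equal_weights_plain_median(self):
        h = make_hset([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.5, 0.9], [0.1] * 3)
        assert weighted_median(h, n_boot=50, seed=0).estimate == pytest.approx(0.5)

    def test_dominant_weight_takes_over(self):
        # one SNP with (almost) infinite weight: the estimate is its ratio
        h = make_hset([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.5, 0.9],
                      [1e-8, 0.1, 0.1])
        assert weighted_median(h, n_boot=50, seed=0).estimate == pytest.approx(
            0.1, abs=1e-6
        )

    def test_too_few_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_hset([1.0], [0.01], [0.1], [0.1]))

    def test_robust_to_invalid_minority(self):
        # 40% of comparably-strong SNPs share a +1 ratio offset: valid
        # instruments keep the weight majority, so the weighted median
        # stays consistent and beats IVW in the vast majority of draws
        wins = 0
        reps = 50
        rng = np.random.default_rng(400)
        for s in range(reps):
            bx = rng.uniform(0.08, 0.12, 20)
            sy = np.full(20, 0.01)
            by = 0.3 * bx + rng.normal(0, sy)
            by[:8] += 1.0 * bx[:8]  # invalid minority
            h = make_hset(bx, np.full(20, 0.002), by, sy)
            med = WeightedMedian(n_boot=2, seed=s).fit(h).estimate_
            res, _ = ivw(h)
            wins += abs(med - 0.3) < abs(res.estimate - 0.3)
        assert wins >= 0.8 * reps

    def test_seeded_bootstrap_reproducible(self):
        h = _random_hset(5, k=10)
        a = weighted_median(h, n_boot=200, seed=7)
        b = weighted_median(h, n_boot=200, seed=7)
        assert a.se == b.se


class TestWeightedMode:
    def test_all_ratios_equal(self):
        h = make_hset([1.0, 1.0, 1.0], [0.01] * 3, [0.4, 0.4, 0.4], [0.1] * 3)
        assert weighted_mode(h, n_boot=20, seed=0).estimate == pytest.approx(0.4)

    def test_majority_cluster_wins(self):
        h = make_hset([1.0] * 4, [0.01] * 4, [0.5, 0.5, 0.5, 2.0], [0.1] * 4)
        est = weighted_mode(h, n_boot=20, seed=0).estimate
        # independent fine-grid density argmax oracle
        from targetmr.mr import _mode_bandwidth
        ratios = np.array([0.5, 0.5, 0.5, 2.0])
        w = np.full(4, 100.0)
        hbw = _mode_bandwidth(ratios, 1.0)
        grid = np.linspace(-1, 3, 40001)
        dens = (
            w[None, :]
            * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / hbw) ** 2)
        ).sum(axis=1)
        oracle = grid[np.argmax(dens)]
        assert est == pytest.approx(oracle, abs=0.02)
        assert est == pytest.approx(0.5, abs=0.1)

    def test_too_few_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_mode(make_hset([1.0, 1.0], [0.01] * 2, [0.1, 0.2],
                                    [0.1] * 2))


class TestCochranQ:
    def test_identical_ratios(self):
        h = make_hset([1.0, 1.0], [0.01] * 2, [0.5, 0.5], [0.1] * 2)
        q, df, p, i2 = cochran_q(h, 0.5)
        assert q == 0.0 and i2 == 0.0 and df == 1

    def test_arithmetic_example(self):
        # ratios 0 and 1 with unit ratio-SEs, about estimate 0.5
        h = make_hset([1.0, 1.0], [0.01] * 2, [0.0, 1.0], [1.0, 1.0])
        q, _, _, _ = cochran_q(h, 0.5)
        assert q == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_direct_summation_oracle(self, seed):
        h = _random_hset(seed, k=40)
        h.df["beta_out"] += np.random.default_rng(seed).normal(
            0, 0.01, size=40
        )  # inject heterogeneity
        res, sens = ivw(h)
        q, df, p, i2 = cochran_q(h, res.estimate)
        ratio = h.df["beta_out"] / h.df["beta_exp"]
        se_r = (h.df["se_out"] / h.df["beta_exp"]).abs()
        q_direct = float((((ratio - res.estimate) / se_r) ** 2).sum())
        assert q == pytest.approx(q_direct, rel=1e-12)
        assert sens.q == pytest.approx(q_direct, rel=1e-12)
        assert i2 == pytest.approx(max(0.0, (q - df) / q), abs=1e-15)


class TestSteiger:
    def test_clear_forward_direction(self):
        h = make_hset([0.1], [0.003], [0.001], [0.003])
        res = steiger(h)
        assert res.direction_correct and res.steiger_pval < 1e-10

    def test_equal_r2_gives_p_one(self):
        h = make_hset([0.05, 0.05], [0.003] * 2, [0.05, 0.05], [0.003] * 2)
        res = steiger(h)
        assert res.steiger_pval == pytest.approx(1.0)
        assert not res.direction_correct  # strict inequality

    def test_per_snp_keep_flags(self):
        h = make_hset([0.1, 0.001], [0.003] * 2, [0.001, 0.1], [0.003] * 2)
        assert h.df["steiger_keep"].tolist() == [True, False]


class TestMRPresso:
    def test_too_few_snps(self):
        h = make_hset([1.0] * 3, [0.01] * 3, [0.1] * 3, [0.1] * 3)
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso(h)

    def test_injected_outlier_flagged_and_corrected(self):
        pair = simulate_instrument_set(
            SimulationConfig(n_snps=20, seed=77), flip_alleles=False
        )
        vid = pair.exposure["variant_id"].iloc[5]
        shifted = inject_outlier(pair, vid, 10.0)
        res = mr_presso(shifted.to_harmonized(), n_sim=1000, seed=3)
        assert vid in res.outlier_ids
        assert res.global_pval < 0.01
        # outlier removed from the corrected fit, whose SE drops sharply
        assert res.corrected_estimate.k == 19
        full, _ = ivw(shifted.to_harmonized())
        assert res.corrected_estimate.se < full.se
        assert res.distortion_pval is not None

    def test_null_global_p_not_extreme(self):
        h = _random_hset(8, k=20)
        res = mr_presso(h, n_sim=500, seed=1)
        assert res.global_pval > 0.01
        assert res.outlier_ids == []
        # no outliers: corrected estimate is the full IVW
        full, _ = ivw(h)
        assert res.corrected_estimate.estimate == pytest.approx(full.estimate)

    def test_seeded_simulation_bitwise_reproducible(self):
        h = _random_hset(2, k=15)
        a = mr_presso(h, n_sim=300, seed=9)
        b = mr_presso(h, n_sim=300, seed=9)
        assert a.global_pval == b.global_pval
        pd.testing.assert_series_equal(
            a.per_snp_outlier_pval, b.per_snp_outlier_pval
        )


class TestResultInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_ci_brackets_estimate_and_p_in_range(self, seed):
        h = _random_hset(seed, k=12)
        for res in [
            ivw(h)[0],
            egger(h)[0],
            weighted_median(h, n_boot=50, seed=seed),
            weighted_mode(h, n_boot=20, seed=seed),
        ]:
            assert res.ci_low <= res.estimate <= res.ci_high
            assert 0 < res.pval <= 1
            assert res.odds_ratio == pytest.approx(np.exp(res.estimate))


class TestSklearnConventions:
    @pytest.mark.parametrize(
        "est",
        [WaldRatio(), IVW(), Egger(), WeightedMedian(n_boot=10),
         WeightedMode(n_boot=5), MRPresso(n_sim=50)],
    )
    def test_get_set_params_and_clone(self, est):
        params = est.get_params()
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(**params)

    def test_fitted_attributes(self):
        h = _random_hset(1, k=10)
        est = IVW().fit(h)
        assert hasattr(est, "estimate_") and hasattr(est, "se_")
        assert est.result_.k == 10
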
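import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from targetmr import simulate
from targetmr.estimators import (cochran_q, egger, ivw, single_variant_scan,
                                 wald_ratio, weighted_median, weighted_mode,
                                 WeakInstrumentError)
from targetmr.sumstats import ValidationError, two_sided_p

from conftest import insts_from_frames, make_inst, make_insts


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(make_inst(be=0.1, bo=0.02, se_o=0.01))
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome(self):
        est = wald_ratio(make_inst(be=0.1, bo=0.0, se_o=0.01))
        assert est.beta == 0.0
        assert est.pval == pytest.approx(1.0)

    def test_second_order_se(self):
        est = wald_ratio(make_inst(be=0.1, se_e=0.02, bo=0.02, se_o=0.01),
                         second_order=True)
        expected = np.sqrt(0.01**2 / 0.1**2 + 0.02**2 * 0.02**2 / 0.1**4)
        assert est.se == pytest.approx(expected)
        assert est.se == pytest.approx(0.1077, abs=1e-4)

    def test_zero_exposure_beta(self):
        with pytest.raises(WeakInstrumentError):
            wald_ratio(make_inst(be=0.0))

    def test_ci_brackets_beta(self):
        est = wald_ratio(make_inst())
        assert est.ci_low <= est.beta <= est.ci_high
        assert est.ci_high - est.beta == pytest.approx(1.959964 * est.se)


class TestIVW:
    def test_closed_form_example(self):
        insts = make_insts([0.1, 0.2], [0.02, 0.03], [0.01, 0.01])
        est = ivw(insts)
        assert est.beta == pytest.approx(0.16, rel=1e-12)
        assert est.se == pytest.approx(0.04472, abs=1e-5)

    def test_single_instrument_equals_wald(self):
        inst = make_inst()
        assert ivw([inst]).beta == wald_ratio(inst).beta
        assert ivw([inst]).se == wald_ratio(inst).se

    def test_identical_instruments(self):
        insts = make_insts([0.1, 0.1, 0.1], [0.02, 0.02, 0.02],
                           [0.01, 0.01, 0.01])
        est = ivw(insts)
        assert est.beta == pytest.approx(0.2, rel=1e-12)
        assert est.q_stat == pytest.approx(0.0, abs=1e-20)

    def test_matches_wls_through_origin_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            m = int(rng.integers(2, 30))
            be = rng.uniform(0.02, 0.3, m) * rng.choice([-1, 1], m)
            bo = rng.normal(0, 0.05, m)
            se_o = rng.uniform(0.005, 0.05, m)
            est = ivw(make_insts(be, bo, se_o))
            fit = sm.WLS(bo, be, weights=1.0 / se_o**2).fit()
            assert est.beta == pytest.approx(fit.params[0], abs=1e-12)

    def test_random_se_geq_fixed(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            m = int(rng.integers(3, 15))
            insts = make_insts(rng.uniform(0.05, 0.3, m),
                               rng.normal(0, 0.05, m),
                               rng.uniform(0.005, 0.05, m))
            assert ivw(insts, model="random").se >= ivw(insts, model="fixed").se

    def test_dl_random_option(self):
        insts = make_insts([0.1, 0.2, 0.15], [0.05, 0.01, 0.06],
                           [0.01, 0.01, 0.01])
        est = ivw(insts, model="random", random_method="dl")
        assert est.tau2 is not None and est.tau2 >= 0
        assert est.method == "ivw_random_dl"

    def test_p_reproduces_beta_over_se(self):
        insts = make_insts([0.1, 0.2], [0.02, 0.03], [0.01, 0.01])
        est = ivw(insts)
        assert est.pval == pytest.approx(two_sided_p(est.beta / est.se),
                                         abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            ivw([])


class TestCochranQ:
    def test_hand_arithmetic(self):
        insts = make_insts([0.1, 0.2], [0.02, 0.03], [0.01, 0.01])
        q, df, p = cochran_q(insts, 0.16)
        assert q == pytest.approx(0.2, rel=1e-12)
        assert df == 1

    def test_homogeneous_zero(self):
        insts = make_insts([0.1, 0.2], [0.02, 0.04], [0.01, 0.01])
        q, df, p = cochran_q(insts, 0.2)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_monotone_in_outlier(self):
        prev = -1.0
        for outlier in (0.05, 0.5, 5.0):
            insts = make_insts([0.1, 0.1], [0.02, outlier * 0.1], [0.01, 0.01])
            q, _, _ = cochran_q(insts, 0.2)
            assert q > prev
            prev = q

    def test_needs_two(self):
        with pytest.raises(ValidationError):
            cochran_q([make_inst()], 0.0)


class TestEgger:
    def test_collinear_through_origin(self):
        insts = make_insts([0.1, 0.2, 0.3], [0.02, 0.04, 0.06],
                           [0.01, 0.01, 0.01])
        est = egger(insts)
        assert est.beta == pytest.approx(0.2, rel=1e-9)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_needs_three(self):
        with pytest.raises(ValidationError):
            egger(make_insts([0.1, 0.2], [0.02, 0.03], [0.01, 0.01]))

    def test_matches_statsmodels_wls(self):
        rng = np.random.default_rng(13)
        be = rng.uniform(0.05, 0.3, 20)
        bo = 0.1 * be + rng.normal(0, 0.02, 20)
        se_o = rng.uniform(0.01, 0.03, 20)
        est = egger(make_insts(be, bo, se_o))
        X = sm.add_constant(be)
        fit = sm.WLS(bo, X, weights=1.0 / se_o**2).fit()
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)

    def test_recovers_directional_offset(self):
        cfg = simulate.SimConfig(true_causal_effect=0.1, n_instruments=50,
                                 pleiotropy_mode="directional",
                                 pleiotropy_sd=0.005, pleiotropy_mean=0.01,
                                 seed=5)
        e, o, truth = simulate.generate_two_sample_gwas(cfg)
        est = egger(insts_from_frames(e, o))
        assert abs(est.egger_intercept - 0.01) < 2 * est.egger_intercept_se

    def test_orientation_invariance(self):
        # flipping the sign of a (be, bo) pair must not change the fit
        be = np.array([0.1, 0.2, 0.3, 0.15])
        bo = np.array([0.03, 0.05, 0.07, 0.02])
        se_o = np.full(4, 0.01)
        a = egger(make_insts(be, bo, se_o))
        be2, bo2 = be.copy(), bo.copy()
        be2[1] *= -1
        bo2[1] *= -1
        b = egger(make_insts(be2, bo2, se_o))
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
        assert a.egger_intercept == pytest.approx(b.egger_intercept, abs=1e-12)


class TestWeightedMedian:
    def test_robust_to_one_outlier(self):
        insts = make_insts([0.1, 0.1, 0.1], [0.01, 0.02, 0.09],
                           [0.01, 0.01, 0.01])
        est = weighted_median(insts, n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.2)

    def test_weight_concentration_limit(self):
        insts = make_insts([0.1, 0.1, 0.1], [0.01, 0.02, 0.09],
                           [1.0, 1e-6, 1.0])
        est = weighted_median(insts, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2, abs=1e-3)

    def test_interpolation_against_cumulative_oracle(self):
        # 4 ratios with crafted weights; oracle = explicit cumulative sum
        theta = np.array([0.1, 0.2, 0.4, 0.8])
        w = np.array([1.0, 2.0, 3.0, 2.0])
        wn = w / w.sum()
        p = np.cumsum(wn) - 0.5 * wn
        k = int(np.searchsorted(p, 0.5))
        expected = theta[k - 1] + (theta[k] - theta[k - 1]) * \
            (0.5 - p[k - 1]) / (p[k] - p[k - 1])
        # encode weights via se_o: w_j = (be/se_o)^2 with be=1
        se_o = 1.0 / np.sqrt(w)
        insts = make_insts(np.ones(4), theta, se_o)
        est = weighted_median(insts, n_boot=10, seed=0)
        assert est.beta == pytest.approx(expected, rel=1e-12)

    def test_needs_three(self):
        with pytest.raises(ValidationError):
            weighted_median(make_insts([0.1, 0.1], [0.02, 0.02], [0.01, 0.01]))

    def test_bootstrap_seed_reproducible(self):
        insts = make_insts([0.1, 0.12, 0.09], [0.02, 0.03, 0.01],
                           [0.01, 0.01, 0.01])
        a = weighted_median(insts, n_boot=200, seed=42)
        b = weighted_median(insts, n_boot=200, seed=42)
        assert a.se == b.se


class TestWeightedMode:
    def test_all_equal(self):
        insts = make_insts([0.1, 0.2, 0.4], [0.02, 0.04, 0.08],
                           [0.01, 0.01, 0.01])
        est = weighted_mode(insts, n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.2, abs=1e-9)

    def test_majority_cluster_wins(self):
        theta = np.array([0.2] * 7 + [0.8] * 3)
        rng = np.random.default_rng(4)
        theta = theta + rng.normal(0, 0.005, 10)
        insts = make_insts(np.ones(10), theta, np.ones(10) * 0.1)
        est = weighted_mode(insts, n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.2, abs=0.05)

    def test_bandwidth_bounded_by_range(self):
        rng = np.random.default_rng(5)
        theta = rng.normal(0.3, 0.1, 8)
        insts = make_insts(np.ones(8), theta, np.ones(8) * 0.1)
        for bf in (0.5, 1.0, 2.0, 4.0):
            est = weighted_mode(insts, bandwidth_factor=bf, n_boot=5, seed=0)
            assert theta.min() <= est.beta <= theta.max()

    def test_dense_grid_oracle(self):
        rng = np.random.default_rng(6)
        theta = np.concatenate([rng.normal(0.2, 0.01, 7),
                                rng.normal(0.8, 0.01, 3)])
        w = np.ones(10)
        insts = make_insts(np.ones(10), theta, np.ones(10))
        est = weighted_mode(insts, n_boot=5, seed=0)
        # oracle: independent dense-grid density maximiser
        s = np.std(theta, ddof=1)
        from scipy.stats import median_abs_deviation
        h = 0.9 * min(s, median_abs_deviation(theta, scale="normal")) * 10**(-0.2)
        grid = np.linspace(theta.min(), theta.max(), 20_001)
        dens = np.sum(np.exp(-0.5 * ((grid[:, None] - theta) / h) ** 2), axis=1)
        assert est.beta == pytest.approx(grid[np.argmax(dens)], abs=2e-3)


class TestSingleVariantScan:
    def test_homogeneous_no_flags(self):
        insts = make_insts([0.1, 0.2, 0.15, 0.12],
                           np.array([0.1, 0.2, 0.15, 0.12]) * 0.2,
                           [0.01] * 4)
        df = single_variant_scan(insts)
        assert not df["influential"].any()

    def test_contaminated_instrument_flagged(self):
        be = np.full(6, 0.1)
        bo = be * 0.2
        bo[3] += 0.3  # large pleiotropic contamination
        df = single_variant_scan(make_insts(be, bo, [0.01] * 6))
        assert df.loc[3, "influential"]

    def test_single_instrument_loo_absent(self):
        df = single_variant_scan([make_inst()])
        assert len(df) == 1
        assert np.isnan(df.loc[0, "loo_beta"])


class TestProperties:
    @given(st.integers(0, 5000))
    @settings(max_examples=30, deadline=None)
    def test_ci_and_p_consistency(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 12))
        insts = make_insts(rng.uniform(0.05, 0.3, m),
                           rng.normal(0, 0.05, m),
                           rng.uniform(0.005, 0.05, m))
        est = ivw(insts)
        assert est.ci_low <= est.beta <= est.ci_high
        assert est.pval == pytest.approx(two_sided_p(est.beta / est.se),
                                         abs=1e-12)
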
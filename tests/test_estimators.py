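import itertools
import math

import numpy as np
import pytest

from mrpipe.estimators import (
    InsufficientInstrumentsError,
    UndefinedRatioError,
    egger,
    estimate_all,
    ivw,
    to_odds_scale,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from mrpipe.estimators import _weighted_median_point, _weighted_mode_point, _mode_bandwidth
from mrpipe.harmonize import harmonize
from mrpipe.instruments import MatrixR2Lookup, SelectionConfig, select_instruments
from mrpipe.simulate import SimConfig, ld_r2_matrix, simulate_triple

from conftest import make_set


class TestWaldRatio:
    def test_division(self):
        est = wald_ratio(make_set([0.1], [0.02], [0.01]).pairs[0])
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome(self):
        est = wald_ratio(make_set([0.25], [0.0], [0.01]).pairs[0])
        assert est.beta == 0.0

    def test_zero_exposure_raises(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(make_set([0.0], [0.01], [0.01]).pairs[0])

    def test_se_matches_monte_carlo(self):
        """Delta-method SE within 5% of the simulated ratio SD at F >> 100."""
        rng = np.random.default_rng(61)
        beta_exp, se_exp = 0.1, 0.005  # |beta/se| = 20
        beta_out, se_out = 0.03, 0.01
        draws = rng.normal(beta_out, se_out, 10**6) / rng.normal(beta_exp, se_exp, 10**6)
        mc_sd = draws.std()
        est = wald_ratio(make_set([beta_exp], [beta_out], [se_out], se_exp=[se_exp]).pairs[0])
        assert est.se == pytest.approx(mc_sd, rel=0.05)


class TestIVW:
    def test_homogeneous_ratios(self):
        iset = make_set([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], [0.01, 0.02, 0.03])
        fe = ivw(iset, random_effects=False)
        mre = ivw(iset, random_effects=True)
        assert fe.beta == pytest.approx(0.5)
        assert fe.heterogeneity_q == pytest.approx(0.0, abs=1e-20)
        assert mre.se == fe.se  # Q=0 -> floor at 1

    def test_two_equal_weights_unweighted_mean(self):
        iset = make_set([0.1, 0.1], [0.01, 0.03], [0.02, 0.02])
        assert ivw(iset).beta == pytest.approx(0.2)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_set([0.1], [0.02], [0.01]))

    def test_equals_wls_oracle_to_10_decimals(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(62)
        beta_exp = rng.normal(0.1, 0.03, 20)
        se_out = rng.uniform(0.005, 0.02, 20)
        beta_out = 0.4 * beta_exp + rng.normal(0, se_out)
        iset = make_set(beta_exp, beta_out, se_out)
        est = ivw(iset, random_effects=False)
        wls = sm.WLS(beta_out, beta_exp, weights=1.0 / se_out**2).fit()
        assert est.beta == pytest.approx(wls.params[0], abs=1e-10)
        # fixed-effect SE equals the unscaled WLS standard error
        se_unscaled = float(np.sqrt(1.0 / np.sum(beta_exp**2 / se_out**2)))
        assert est.se == pytest.approx(se_unscaled, abs=1e-12)

    def test_mre_se_geq_fe_se(self):
        rng = np.random.default_rng(63)
        for _ in range(20):
            k = int(rng.integers(2, 15))
            iset = make_set(
                rng.normal(0.1, 0.05, k) + 0.05,
                rng.normal(0.0, 0.05, k),
                rng.uniform(0.005, 0.03, k),
            )
            assert ivw(iset, True).se >= ivw(iset, False).se

    def test_invariant_to_ordering_and_flips(self):
        rng = np.random.default_rng(64)
        beta_exp = rng.normal(0.1, 0.03, 12)
        se_out = rng.uniform(0.01, 0.02, 12)
        beta_out = 0.3 * beta_exp + rng.normal(0, se_out)
        base = ivw(make_set(beta_exp, beta_out, se_out)).beta
        perm = rng.permutation(12)
        assert ivw(make_set(beta_exp[perm], beta_out[perm], se_out[perm])).beta == pytest.approx(base, abs=1e-14)
        sign = np.where(rng.random(12) < 0.5, -1, 1)  # allele-flip both betas
        assert ivw(make_set(beta_exp * sign, beta_out * sign, se_out)).beta == pytest.approx(base, abs=1e-14)


class TestEgger:
    def test_exact_line_recovery(self):
        beta_exp = np.array([0.05, 0.08, 0.1, 0.15, 0.2])
        beta_out = 0.01 + 0.5 * beta_exp
        est = egger(make_set(beta_exp, beta_out, np.full(5, 0.01)))
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.01, abs=1e-10)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_set([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))

    def test_matches_wls_with_intercept_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(65)
        beta_exp = np.abs(rng.normal(0.1, 0.04, 25)) + 0.01
        se_out = rng.uniform(0.005, 0.02, 25)
        beta_out = 0.02 + 0.3 * beta_exp + rng.normal(0, se_out)
        est = egger(make_set(beta_exp, beta_out, se_out))
        wls = sm.WLS(beta_out, sm.add_constant(beta_exp), weights=1.0 / se_out**2).fit()
        assert est.beta == pytest.approx(wls.params[1], abs=1e-10)
        assert est.egger_intercept == pytest.approx(wls.params[0], abs=1e-10)

    def _intercepts(self, pleio_mode, pleio_mean, n_seeds=100):
        # outcome_p_exclude disabled: that screen would truncate the most
        # pleiotropic SNPs and attenuate the very intercept under test
        sel_config = SelectionConfig(outcome_p_exclude=None)
        intercepts = []
        for seed in range(n_seeds):
            config = SimConfig(
                n_snps=120, n_instruments=60, pleio_mode=pleio_mode,
                pleio_mean=pleio_mean, pleio_sd=0.01, seed=7000 + seed,
            )
            exposure, _, outcome, truth = simulate_triple(config)
            lookup = MatrixR2Lookup(truth.snp_ids, ld_r2_matrix(truth))
            selection = select_instruments(exposure, outcome, lookup, sel_config)
            iset, _ = harmonize(selection.instruments, outcome)
            if len(iset) >= 3:
                intercepts.append(egger(iset).egger_intercept)
        return np.array(intercepts)

    def test_balanced_pleiotropy_intercept_near_zero(self):
        intercepts = self._intercepts("balanced", 0.0)
        mc_se = intercepts.std(ddof=1) / math.sqrt(intercepts.size)
        assert abs(intercepts.mean()) < 3 * mc_se

    def test_directional_pleiotropy_intercept_recovered(self):
        intercepts = self._intercepts("directional", 0.02)
        mc_se = intercepts.std(ddof=1) / math.sqrt(intercepts.size)
        assert abs(intercepts.mean() - 0.02) < 3 * mc_se


class TestWeightedMedian:
    def test_equal_weights_median(self):
        iset = make_set([0.1, 0.1, 0.1], [0.01, 0.02, 0.09], [0.02, 0.02, 0.02])
        est = weighted_median(iset, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_dominant_weight_returns_its_ratio(self):
        # first SNP's weight share: (0.3/0.01)^2 vs two (0.1/0.02)^2 -> ~97%
        iset = make_set([0.3, 0.1, 0.1], [0.3 * 0.37, 0.05, 0.09], [0.01, 0.02, 0.02])
        est = weighted_median(iset, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.37)

    def test_interpolates_at_exact_boundary(self):
        point = _weighted_median_point(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4))
        assert point == pytest.approx(2.5)

    def test_insufficient(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_set([0.1, 0.1], [0.01, 0.01], [0.01, 0.01]))

    def test_breakdown_property(self):
        """60% valid weight at ratio 0.3 + 40% outliers: the weighted median
        stays near 0.3 while IVW is pulled away, across 100 seeds."""
        wm_ok = ivw_biased = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(8000 + seed)
            k, n_bad = 20, 8
            beta_exp = rng.uniform(0.08, 0.12, k)
            se_out = np.full(k, 0.01)
            beta_out = 0.3 * beta_exp + rng.normal(0, se_out)
            beta_out[:n_bad] += 2.0 * beta_exp[:n_bad]  # ratio shifted by +2
            iset = make_set(beta_exp, beta_out, se_out)
            wm = weighted_median(iset, n_boot=200, seed=seed)
            iv = ivw(iset, random_effects=True)
            if abs(wm.beta - 0.3) <= 3 * wm.se:
                wm_ok += 1
            if abs(iv.beta - 0.3) > 3 * iv.se:
                ivw_biased += 1
        assert wm_ok >= 95
        assert ivw_biased >= 95


class TestWeightedMode:
    def test_all_ratios_equal(self):
        iset = make_set([0.1, 0.2, 0.3], [0.1 * 0.4, 0.2 * 0.4, 0.3 * 0.4],
                        [0.01, 0.01, 0.01])
        est = weighted_mode(iset, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.4, abs=1e-6)

    def test_majority_cluster(self):
        iset = make_set([1.0, 1.0, 1.0, 1.0], [0.30, 0.31, 0.29, 1.5],
                        [1.0, 1.0, 1.0, 1.0])
        est = weighted_mode(iset, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.30, abs=0.02)

    def test_insufficient(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_mode(make_set([0.1, 0.1], [0.01, 0.01], [0.01, 0.01]))

    def test_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(66)
        k = 15
        beta_exp = rng.uniform(0.05, 0.15, k)
        se_out = rng.uniform(0.005, 0.02, k)
        beta_out = 0.25 * beta_exp + rng.normal(0, se_out)
        ratios = beta_out / beta_exp
        weights = beta_exp**2 / se_out**2
        point = _weighted_mode_point(ratios, weights, 1.0)

        # independent dense-grid argmax of the same kernel density
        h = _mode_bandwidth(ratios, weights, 1.0)
        w = weights / weights.sum()
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 100_001)
        dens = np.array([
            np.sum(w * np.exp(-0.5 * ((x - ratios) / h) ** 2)) for x in grid[::100]
        ])
        coarse = grid[::100][np.argmax(dens)]
        fine = grid[np.abs(grid - coarse) < 0.05]
        dens_fine = [np.sum(w * np.exp(-0.5 * ((x - ratios) / h) ** 2)) for x in fine]
        oracle = fine[int(np.argmax(dens_fine))]
        assert point == pytest.approx(oracle, abs=1e-3)


class TestOddsScale:
    def test_known_rounding(self):
        est = ivw(make_set([0.1, 0.1], [0.0068, 0.0068], [0.02, 0.02]))
        assert round(est.or_, 2) == 1.07  # exp(0.068)

    def test_null_beta(self):
        est = ivw(make_set([0.1, 0.1], [0.0, 0.0], [0.02, 0.02]))
        assert est.or_ == pytest.approx(1.0)

    def test_monotone_in_beta(self):
        import dataclasses

        base = ivw(make_set([0.1, 0.1], [0.01, 0.01], [0.02, 0.02]))
        ors = []
        for beta in np.linspace(-1, 1, 41):
            est = dataclasses.replace(base, beta=float(beta))
            ors.append(to_odds_scale(est).or_)
        assert all(a < b for a, b in zip(ors, ors[1:]))
        mid = to_odds_scale(dataclasses.replace(base, beta=0.143))
        assert mid.or_ == pytest.approx(math.exp(0.143))

    def test_ci_consistency(self):
        est = ivw(make_set([0.1, 0.1], [0.01, 0.03], [0.02, 0.02]))
        assert est.or_ci_low == pytest.approx(math.exp(est.ci_low))
        assert est.or_ci_high == pytest.approx(math.exp(est.ci_high))
        assert est.ci_low <= est.beta <= est.ci_high


class TestCrossEstimator:
    def test_dominant_instrument_convergence(self):
        """One SNP with ~all the weight: ratio-based estimators collapse to
        its Wald ratio (Egger excluded: its intercept absorbs the anchor)."""
        beta_exp = np.array([0.5, 0.05, 0.06, 0.04])
        se_out = np.array([1e-4, 0.05, 0.05, 0.05])
        beta_out = np.array([0.5 * 0.37, 0.01, -0.02, 0.015])
        iset = make_set(beta_exp, beta_out, se_out)
        target = 0.37
        assert ivw(iset).beta == pytest.approx(target, abs=1e-3)
        assert weighted_median(iset, n_boot=50, seed=1).beta == pytest.approx(target, abs=1e-6)
        assert weighted_mode(iset, n_boot=50, seed=1).beta == pytest.approx(target, abs=1e-3)

    def test_estimators_agree_without_pleiotropy(self, effect_triple, effect_r2):
        exposure, _, outcome, _ = effect_triple
        selection = select_instruments(exposure, outcome, effect_r2, SelectionConfig())
        iset, _ = harmonize(selection.instruments, outcome)
        ests = estimate_all(iset, n_boot=300, seed=3)
        for a, b in itertools.combinations(ests.values(), 2):
            joint = math.sqrt(a.se**2 + b.se**2)
            assert abs(a.beta - b.beta) <= 2 * joint
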
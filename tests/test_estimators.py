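"""Estimator correctness: hand oracles, independent solves, and invariances."""

import numpy as np
import pytest
from conftest import make_harmonized, random_harmonized

from mrmediate import (
    EstimationError,
    InputError,
    egger,
    ivw,
    mr_power,
    raps,
    wald_ratios,
    weighted_median,
)


class TestWaldRatios:
    def test_first_order_delta_arithmetic(self):
        h = make_harmonized([0.1], [0.01], [0.02], [0.01])
        r = wald_ratios(h)
        assert r.loc[0, "ratio"] == pytest.approx(0.2)
        assert r.loc[0, "ratio_se"] == pytest.approx(0.1)

    def test_zero_outcome_beta_gives_zero_ratio(self):
        h = make_harmonized([0.1], [0.01], [0.0], [0.01])
        assert wald_ratios(h).loc[0, "ratio"] == 0.0

    def test_zero_exposure_beta_excluded(self):
        h = make_harmonized([0.1, 0.0], [0.01] * 2, [0.02, 0.05], [0.01] * 2)
        r = wald_ratios(h)
        assert r["variant_id"].tolist() == ["rs0001"]


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        h = make_harmonized([0.1], [0.01], [0.02], [0.01])
        res = ivw(h)
        assert res.beta == pytest.approx(0.2)
        assert res.se == pytest.approx(0.1)
        assert res.n_snps == 1

    def test_two_snp_hand_weighted_mean(self):
        # ratios 0.1 (se 0.05) and 0.3 (se 0.1): weights 400 and 100
        h = make_harmonized([1.0, 1.0], [1e-8] * 2, [0.1, 0.3], [0.05, 0.1])
        res = ivw(h, model="fixed")
        assert res.beta == pytest.approx(0.14)
        assert res.se == pytest.approx(np.sqrt(1 / 500.0))

    def test_fixed_estimate_equals_closed_form_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            h = random_harmonized(rng, j=int(rng.integers(3, 30)))
            res = ivw(h, model="fixed")
            r = wald_ratios(h)
            w = 1.0 / r["ratio_se"] ** 2
            assert res.beta == pytest.approx(float((w * r["ratio"]).sum() / w.sum()), rel=1e-12)

    def test_many_instruments_recover_true_slope(self):
        rng = np.random.default_rng(123)
        j = 10_000
        gamma = rng.normal(0, 0.1, j)
        gamma[np.abs(gamma) < 0.02] += 0.05
        se_g, se_G = 0.002, 0.01
        h = make_harmonized(
            gamma + rng.normal(0, se_g, j),
            np.full(j, se_g),
            0.2 * gamma + rng.normal(0, se_G, j),
            np.full(j, se_G),
        )
        res = ivw(h)
        assert 0.19 < res.beta < 0.21

    def test_empty_set_is_input_error(self):
        h = make_harmonized([0.0], [0.01], [0.1], [0.01])  # only zero-gamma row
        with pytest.raises(InputError):
            ivw(h)

    def test_mre_se_never_below_fixed(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            h = random_harmonized(rng, j=15)
            assert ivw(h, "multiplicative_random").se >= ivw(h, "fixed").se - 1e-15


class TestEgger:
    def test_exact_proportional_rows(self):
        gamma = np.array([0.05, 0.1, 0.2, 0.3])
        h = make_harmonized(gamma, [0.01] * 4, 0.3 * gamma, [0.01] * 4)
        res = egger(h)
        assert res.beta == pytest.approx(0.3, abs=1e-10)
        assert res.extras["egger_intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_exact_affine_rows(self):
        gamma = np.array([0.05, 0.1, 0.2, 0.3])
        h = make_harmonized(gamma, [0.01] * 4, 0.05 + 0.3 * gamma, [0.01] * 4)
        res = egger(h)
        assert res.beta == pytest.approx(0.3, abs=1e-10)
        assert res.extras["egger_intercept"] == pytest.approx(0.05, abs=1e-10)

    def test_matches_normal_equations_solve(self):
        rng = np.random.default_rng(17)
        h = random_harmonized(rng, j=5)
        res = egger(h)
        gamma = h.df["beta_exp"].to_numpy().copy()
        Gamma = h.df["beta_out"].to_numpy().copy()
        flip = gamma < 0
        gamma[flip] *= -1
        Gamma[flip] *= -1
        w = 1.0 / h.df["se_out"].to_numpy() ** 2
        X = np.column_stack([np.ones(5), gamma])
        coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * Gamma))
        assert res.extras["egger_intercept"] == pytest.approx(coef[0], rel=1e-9)
        assert res.beta == pytest.approx(coef[1], rel=1e-9)

    def test_requires_three_rows(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.02, 0.04], [0.01] * 2)
        with pytest.raises(InputError, match="3"):
            egger(h)


def brute_force_weighted_median(ratios, weights):
    """Independent cumulative-weight search, written as an explicit scan:
    sort the (ratio, weight) pairs, walk the half-weight-offset cumulative
    sums until they bracket one half, and interpolate linearly."""
    pairs = sorted(zip(ratios, weights))
    total = sum(w for _, w in pairs)
    s_prev = None
    r_prev = None
    cum = 0.0
    for r, w in pairs:
        s = (cum + w / 2.0) / total
        if s >= 0.5:
            if s_prev is None:
                return float(r)
            return float(r_prev + (r - r_prev) * (0.5 - s_prev) / (s - s_prev))
        cum += w
        s_prev, r_prev = s, r
    return float(pairs[-1][0])


class TestWeightedMedian:
    def test_degenerate_distribution(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.01] * 3, [0.03, 0.06, 0.12], [0.01] * 3)
        res = weighted_median(h, n_boot=50, seed=0)
        assert res.beta == pytest.approx(0.3)

    def test_equal_weight_three_ratios(self):
        # ratios {0.1, 0.2, 0.9} with equal weights -> middle one
        h = make_harmonized([1.0] * 3, [1e-6] * 3, [0.1, 0.2, 0.9], [0.05] * 3)
        res = weighted_median(h, n_boot=50, seed=0)
        assert res.beta == pytest.approx(0.2)

    def test_matches_brute_force_minimizer(self):
        rng = np.random.default_rng(31)
        h = random_harmonized(rng, j=11)
        res = weighted_median(h, n_boot=50, seed=0)
        from mrmediate import wald_ratios

        r = wald_ratios(h)
        expected = brute_force_weighted_median(
            r["ratio"], 1.0 / r["ratio_se"] ** 2
        )
        assert res.beta == pytest.approx(expected, abs=2e-5)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        h = random_harmonized(rng, j=9)
        perm = rng.permutation(9)
        h2 = h.subset(h.df.index[perm])
        assert weighted_median(h, n_boot=10, seed=1).beta == pytest.approx(
            weighted_median(h2, n_boot=10, seed=1).beta, rel=1e-12
        )


def grid_search_raps(h, lo=-2.0, hi=2.0, step=1e-4):
    gamma = h.df["beta_exp"].to_numpy()
    Gamma = h.df["beta_out"].to_numpy()
    vg = h.df["se_exp"].to_numpy() ** 2
    vG = h.df["se_out"].to_numpy() ** 2
    grid = np.arange(lo, hi + step, step)
    t = (Gamma[None, :] - grid[:, None] * gamma[None, :]) / np.sqrt(
        vG[None, :] + grid[:, None] ** 2 * vg[None, :]
    )
    obj = (t**2).sum(axis=1)
    return float(grid[np.argmin(obj)])


class TestRAPS:
    def test_noiseless_rows_recover_slope(self):
        gamma = np.array([0.05, 0.1, 0.2, 0.3])
        h = make_harmonized(gamma, [1e-8] * 4, 0.3 * gamma, [1e-8] * 4)
        assert raps(h).beta == pytest.approx(0.3, abs=1e-6)

    def test_agrees_with_ivw_when_exposure_noise_vanishes(self):
        rng = np.random.default_rng(12)
        h = random_harmonized(rng, j=30, se_g=1e-10)
        assert raps(h).beta == pytest.approx(ivw(h, "fixed").beta, abs=1e-3)

    def test_matches_grid_search(self):
        rng = np.random.default_rng(44)
        h = random_harmonized(rng, j=50)
        assert raps(h).beta == pytest.approx(grid_search_raps(h), abs=2e-4)

    def test_boundary_hit_raises(self):
        # slope ~ 20 lies outside the default bracket
        gamma = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(gamma, [1e-8] * 3, 20.0 * gamma, [1e-6] * 3)
        with pytest.raises(EstimationError, match="bracket"):
            raps(h)

    def test_huber_loss_resists_one_outlier(self):
        gamma = np.full(12, 0.2)
        Gamma = 0.3 * gamma
        Gamma[0] += 0.5
        h = make_harmonized(gamma, [1e-4] * 12, Gamma, [0.01] * 12)
        assert abs(raps(h, loss="huber").beta - 0.3) < abs(raps(h, loss="l2").beta - 0.3)


class TestSignFlipEquivariance:
    @pytest.mark.parametrize("estimator", ["ivw", "egger", "weighted_median", "raps"])
    def test_negating_exposure_negates_estimate(self, estimator):
        rng = np.random.default_rng(61)
        h = random_harmonized(rng, j=12)
        df2 = h.df.copy()
        df2["beta_exp"] = -df2["beta_exp"]
        df2["eaf"] = 1.0 - df2["eaf"]
        h2 = h.subset(slice(None))
        h2.df = df2
        fns = {
            "ivw": lambda x: ivw(x),
            "egger": lambda x: egger(x),
            "weighted_median": lambda x: weighted_median(x, n_boot=10, seed=2),
            "raps": lambda x: raps(x),
        }
        b1 = fns[estimator](h).beta
        b2 = fns[estimator](h2).beta
        assert b2 == pytest.approx(-b1, rel=1e-9, abs=1e-12)


class TestPower:
    def test_null_effect_gives_size(self):
        assert mr_power(10_000, 0.1, 0.02, 0.0, alpha=0.05) == pytest.approx(0.05)

    def test_monotone_in_noncentrality(self):
        p1 = mr_power(10_000, 0.1, 0.02, 0.2)
        p2 = mr_power(20_000, 0.1, 0.02, 0.2)
        assert p2 >= p1
        assert mr_power(10_000_000, 0.5, 0.5, 1.0) > 0.999

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            mr_power(1000, 1.5, 0.02, 0.2)
        with pytest.raises(InputError):
            mr_power(1000, 0.1, 0.0, 0.2)

    def test_agrees_with_empirical_rejection_rate(self):
        """The closed-form power should match the empirical rejection rate of
        the IVW z-test over simulated datasets within +-0.03."""
        rng = np.random.default_rng(777)
        n_out, cf, beta = 20_000, 0.1, 0.08
        j, gamma_sd = 30, 0.08
        # instrument R2 on the exposure: sum of 2 maf(1-maf) gamma^2 ... here
        # exposure is standardized so R2_j ~ gamma_j^2 * 2 maf (1-maf); use
        # fixed gammas/mafs so R2 is exact.
        gamma = np.abs(rng.normal(0, gamma_sd, j)) + 0.03
        maf = rng.uniform(0.1, 0.5, j)
        r2 = float(np.sum(2 * maf * (1 - maf) * gamma**2))
        power = mr_power(n_out, cf, r2, beta, alpha=0.05)
        se_G = 1.0 / np.sqrt(2 * n_out * cf * (1 - cf) * maf * (1 - maf))
        rejections = 0
        reps = 2000
        for _ in range(reps):
            Gamma_hat = beta * gamma + rng.normal(0, se_G)
            h = make_harmonized(gamma, np.full(j, 1e-9), Gamma_hat, se_G)
            res = ivw(h, model="fixed")
            rejections += res.pvalue < 0.05
        assert abs(rejections / reps - power) <= 0.03
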
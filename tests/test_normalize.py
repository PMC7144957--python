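"""ZN parameter estimation and application."""

import numpy as np
import pandas as pd
import pytest

from zipfnorm import (
    ExpressionProfile,
    NormalizationParams,
    SyntheticSpec,
    compute_zipf,
    estimate_gamma,
    estimate_log_sigma,
    fit_tail,
    generate,
    normalize_matrix,
    normalize_pair,
    normalize_profile,
    select_reference,
)

from conftest import ols_two_var, pareto_sample, zero_inflated_profile


def make_fit(slope):
    from zipfnorm.zipf_core import TailFit

    return TailFit(slope=slope, intercept=0.0, rank_cutoff_log=6.0, n_points=20, r_squared=1.0)


class TestEstimateGamma:
    def test_identical_tails_give_one(self):
        assert estimate_gamma(make_fit(-1.7), make_fit(-1.7)) == pytest.approx(1.0)

    def test_published_lcl_slopes(self):
        # reference slope -1.734, target slope -1.730 -> 0.9977 to 4 d.p.
        assert estimate_gamma(make_fit(-1.734), make_fit(-1.730)) == pytest.approx(
            0.9977, abs=5e-5
        )

    def test_orientation_equalizes_slopes(self):
        # target tail slope -1 vs reference -2: exponent 0.5 makes the
        # transformed target slope (-1)/0.5 = -2 match the reference
        gamma = estimate_gamma(make_fit(-2.0), make_fit(-1.0))
        assert gamma == pytest.approx(0.5)
        assert -1.0 / gamma == pytest.approx(-2.0)

    def test_non_negative_slope_rejected(self):
        with pytest.raises(ValueError, match="strictly negative"):
            estimate_gamma(make_fit(0.1), make_fit(-1.5))


class TestEstimateLogSigma:
    def test_self_pair_gives_zero(self, rng):
        curve = compute_zipf(zero_inflated_profile(rng, n_genes=3000, zero_fraction=0.4))
        assert estimate_log_sigma(curve, curve) == pytest.approx(0.0, abs=1e-8)

    def test_exact_scalar_multiple_recovers_log_c(self):
        # exact power-law grid so the pooled tails are parallel lines
        r = np.arange(1, 200)
        x = np.exp((9 - np.log(r)) / 1.7)
        c = 3.7
        curve_x = compute_zipf(ExpressionProfile("x", x))
        curve_y = compute_zipf(ExpressionProfile("y", c * x))
        assert estimate_log_sigma(curve_x, curve_y) == pytest.approx(np.log(c), abs=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(5):
            cx = compute_zipf(zero_inflated_profile(rng, 4000, 0.5, sample_id="x"))
            cy = compute_zipf(zero_inflated_profile(rng, 4000, 0.5, sample_id="y"))
            got = estimate_log_sigma(cx, cy)
            mx = np.log(cx.ranks) < 6
            my = np.log(cy.ranks) < 6
            z = np.concatenate([np.log(cx.values[mx]), np.log(cy.values[my])])
            r = np.concatenate([np.log(cx.ranks[mx]), np.log(cy.ranks[my])])
            g = np.concatenate([np.zeros(mx.sum()), np.ones(my.sum())])
            coef = ols_two_var(z, r, g)
            assert got == pytest.approx(coef[2], abs=1e-10)


class TestNormalizeProfile:
    def params(self, sigma, gamma, method="ZN-full"):
        return NormalizationParams(sigma=sigma, gamma=gamma, method=method, reference_id="r")

    def test_identity(self, rng):
        prof = zero_inflated_profile(rng, 500, 0.3)
        out = normalize_profile(prof, self.params(1.0, 1.0))
        np.testing.assert_array_equal(out.counts, prof.counts)

    def test_power_and_rescale(self):
        out = normalize_profile(
            ExpressionProfile("p", np.array([0.0, 4.0])), self.params(4.0, 0.5)
        )
        np.testing.assert_allclose(out.counts, [0.0, 1.0])

    def test_gamma_one_is_pure_rescaling(self, rng):
        prof = zero_inflated_profile(rng, 500, 0.3)
        out = normalize_profile(prof, self.params(2.5, 1.0))
        np.testing.assert_allclose(out.counts, prof.counts / 2.5)

    def test_zeros_and_order_preserved(self, rng):
        prof = zero_inflated_profile(rng, 1000, 0.5)
        out = normalize_profile(prof, self.params(0.7, 1.3))
        assert np.all(out.counts[prof.counts == 0] == 0.0)
        pos = prof.counts > 0
        assert np.array_equal(
            np.argsort(out.counts[pos]), np.argsort(prof.counts[pos])
        )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            self.params(0.0, 1.0)
        with pytest.raises(ValueError, match="linear"):
            self.params(1.0, 2.0, method="TC")


class TestSelectReference:
    def test_fewest_zeros_with_tie_by_order(self):
        m = pd.DataFrame(
            {"a": [0, 0, 0, 1], "b": [1, 2, 3, 0], "c": [0, 1, 2, 3]},
            index=list("wxyz"),
        )
        assert select_reference(m) == "b"
        m2 = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
        assert select_reference(m2) == "a"

    def test_user_id(self):
        m = pd.DataFrame({"s7": [1.0], "s8": [2.0]})
        assert select_reference(m, "s7") == "s7"
        with pytest.raises(ValueError, match="unknown reference"):
            select_reference(m, "s9")


class TestNormalizeMatrix:
    def synthetic(self, sigmas, gammas, seed=11, n_genes=20000):
        spec = SyntheticSpec(
            n_genes=n_genes,
            n_samples=len(sigmas),
            sigma_per_sample=np.asarray(sigmas, float),
            gamma_per_sample=np.asarray(gammas, float),
            rounding="continuous",
            seed=seed,
        )
        return generate(spec)[0]

    def test_identical_columns_unchanged(self):
        matrix = self.synthetic([1.0, 1.0], [1.0, 1.0])
        out, params = normalize_matrix(matrix, "s01")
        np.testing.assert_allclose(out["s02"], matrix["s02"], rtol=1e-8)
        assert params[1].sigma == pytest.approx(1.0, abs=1e-8)

    def test_self_normalization_params_are_identity(self):
        matrix = self.synthetic([1.0, 1.0], [1.0, 1.0])
        _, params = normalize_matrix(matrix, "s01", scheme="full")
        assert params[1].sigma == pytest.approx(1.0, abs=1e-8)
        assert params[1].gamma == pytest.approx(1.0, abs=1e-8)

    def test_known_distortions_recovered(self):
        sigmas = [1.0, 0.5, 2.2]
        gammas = [1.0, 1.08, 0.93]
        matrix = self.synthetic(sigmas, gammas, n_genes=50000)
        _, params = normalize_matrix(matrix, "s01", scheme="full")
        for p, s_true, g_true in zip(params[1:], sigmas[1:], gammas[1:]):
            assert abs(p.sigma - s_true) / s_true < 0.10
            assert abs(p.gamma - g_true) < 0.05

    def test_noise_free_pair_restores_reference_tail(self):
        # Y = sigma * X**(1/gamma) built from a continuous power-law sample
        rng = np.random.default_rng(5)
        x = np.concatenate([pareto_sample(rng, 2.7, 10.0, 3000), np.zeros(3000)])
        sigma_t, gamma_t = 1.9, 1.07
        y = np.where(x > 0, sigma_t * x ** (1.0 / gamma_t), 0.0)
        ref = ExpressionProfile("x", x)
        tgt = ExpressionProfile("y", y)
        p = normalize_pair(ref, tgt, scheme="full")
        assert p.sigma == pytest.approx(sigma_t, rel=1e-6)
        assert p.gamma == pytest.approx(gamma_t, rel=1e-6)
        restored = normalize_profile(tgt, p)
        pos = x > 0
        np.testing.assert_allclose(restored.counts[pos], x[pos], rtol=1e-6)

    def test_composition_of_linear_factors(self, rng):
        prof = zero_inflated_profile(rng, 800, 0.4)
        p1 = NormalizationParams(sigma=2.0, gamma=1.0, method="ZN-linear", reference_id="r")
        p2 = NormalizationParams(sigma=3.0, gamma=1.0, method="ZN-linear", reference_id="r")
        p12 = NormalizationParams(sigma=6.0, gamma=1.0, method="ZN-linear", reference_id="r")
        chained = normalize_profile(normalize_profile(prof, p1), p2)
        direct = normalize_profile(prof, p12)
        np.testing.assert_allclose(chained.counts, direct.counts, rtol=1e-12)

    def test_failing_column_is_named(self):
        matrix = self.synthetic([1.0, 1.0], [1.0, 1.0], n_genes=20000)
        matrix["s02"] = 0.0
        matrix.iloc[0, 1] = 5.0
        with pytest.raises(ValueError, match="s02"):
            normalize_matrix(matrix, "s01")
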
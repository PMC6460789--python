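"""EM engine: WLS correctness, monotone likelihood, recovery, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surromix import (
    DegenerateEMError,
    MixtureFit,
    SingularDesignError,
    bic,
    em_fit,
    fit_linear,
    identify_informative_component,
    modal_assignment,
    relative_entropy,
)
from surromix.mixture_engine import InformativeTieWarning, m_step
from surromix.synthetic_cohort import BETA_I_DEFAULT, BETA_V_DEFAULT

_LOG2PI = np.log(2 * np.pi)


class TestFitLinear:
    def test_exact_interpolation(self):
        z = np.array([0.0, 1.0, 2.0])
        fit = fit_linear(z, 2.0 * z)
        np.testing.assert_allclose(fit.coefficients, [0.0, 2.0], atol=1e-10)
        assert fit.residual_sd < 1e-8  # floored near zero

    def test_three_point_normal_equations(self):
        # hand-solved: slope 1/2, intercept 7/6
        z = np.array([0.0, 1.0, 2.0])
        y = np.array([1.0, 2.0, 2.0])
        fit = fit_linear(z, y)
        np.testing.assert_allclose(fit.coefficients, [7.0 / 6.0, 0.5], atol=1e-12)

    def test_unit_weights_equal_unweighted(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((50, 3))
        y = rng.standard_normal(50)
        a = fit_linear(Z, y)
        b = fit_linear(Z, y, weights=np.ones(50))
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-12)
        np.testing.assert_allclose(a.residual_sd, b.residual_sd, atol=1e-12)

    def test_singular_design(self):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((40, 2))
        Z = np.column_stack([Z, Z[:, 0]])  # exact collinearity
        with pytest.raises(SingularDesignError):
            fit_linear(Z, rng.standard_normal(40))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(np.arange(5.0), np.arange(5.0), weights=np.zeros(5))


class TestEMFit:
    def test_k1_equals_ols(self):
        rng = np.random.default_rng(2)
        Z = rng.standard_normal((120, 4))
        y = Z @ rng.standard_normal(4) + rng.standard_normal(120)
        ols = fit_linear(Z, y)
        em = em_fit(Z, y, K=1, n_starts=1, seed=0)
        np.testing.assert_allclose(em.coefficients[0], ols.coefficients, atol=1e-8)
        np.testing.assert_allclose(em.residual_sds[0], ols.residual_sd, atol=1e-8)

    def test_planted_recovery_and_posterior_sharpness(self, planted_crossing, crossing_fit):
        z, y, labels = planted_crossing
        fit = crossing_fit
        slopes = np.sort(fit.slopes[:, 0])
        np.testing.assert_allclose(slopes, [-2.0, 2.0], atol=0.1)
        # oracle: posterior sharpness achievable under the TRUE model
        dens_pos = np.exp(-0.5 * ((y - 2 * z[:, 0]) / 0.5) ** 2)
        dens_neg = np.exp(-0.5 * ((y + 2 * z[:, 0]) / 0.5) ** 2)
        tau_true = np.maximum(dens_pos, dens_neg) / (dens_pos + dens_neg)
        frac_true = (tau_true > 0.95).mean()
        frac_fit = (fit.posteriors.max(axis=1) > 0.95).mean()
        assert abs(frac_fit - frac_true) < 0.05

    def test_oracle_equivalence_per_label_ols(self, planted_crossing):
        z, y, labels = planted_crossing
        tau = np.column_stack([labels, ~labels]).astype(float)
        coefs, sds, weights = m_step(z, y, tau)
        for k, mask in enumerate([labels, ~labels]):
            ols = fit_linear(z[mask], y[mask])
            np.testing.assert_allclose(coefs[k], ols.coefficients, atol=1e-10)
            np.testing.assert_allclose(sds[k], ols.residual_sd, atol=1e-10)
        np.testing.assert_allclose(weights, [labels.mean(), 1 - labels.mean()])

    def test_monotone_loglik_all_starts(self, crossing_fit):
        for path in crossing_fit.loglik_paths:
            diffs = np.diff(path)
            assert np.all(diffs >= -1e-8 * np.maximum(1.0, np.abs(path[:-1])))

    def test_nesting_k2_beats_k1(self, planted_crossing):
        z, y, _ = planted_crossing
        ll1 = em_fit(z, y, K=1, n_starts=1, seed=0).log_likelihood
        ll2 = em_fit(z, y, K=2, n_starts=5, seed=0).log_likelihood
        assert ll2 >= ll1 - 1e-6

    def test_posterior_and_weight_simplex(self, crossing_fit):
        np.testing.assert_allclose(crossing_fit.posteriors.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(crossing_fit.mixing_weights.sum(), 1.0, atol=1e-10)

    def test_scale_equivariance(self, planted_crossing):
        # pin the iteration count (tol below reachable precision) so both
        # runs follow the same EM path and the comparison is exact
        z, y, _ = planted_crossing
        a = em_fit(z, y, K=2, n_starts=3, tol=1e-300, max_iter=60, seed=5)
        b = em_fit(z, 10.0 * y, K=2, n_starts=3, tol=1e-300, max_iter=60, seed=5)
        np.testing.assert_allclose(
            b.coefficients, 10.0 * a.coefficients, rtol=1e-6, atol=1e-8
        )
        np.testing.assert_allclose(b.residual_sds, 10.0 * a.residual_sds, rtol=1e-6)
        np.testing.assert_allclose(b.posteriors, a.posteriors, atol=1e-6)

    def test_degenerate_data_raises(self):
        z = np.linspace(0, 1, 30)
        with pytest.raises(DegenerateEMError):
            em_fit(z, np.zeros(30), K=2, n_starts=3, seed=0)

    def test_too_small_n(self):
        with pytest.raises(DegenerateEMError):
            em_fit(np.arange(5.0), np.arange(5.0), K=2, seed=0)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=5, deadline=None)
    def test_determinism(self, seed):
        rng = np.random.default_rng(9)
        z = rng.standard_normal((80, 1))
        y = rng.standard_normal(80)
        a = em_fit(z, y, K=2, n_starts=2, max_iter=50, seed=seed)
        b = em_fit(z, y, K=2, n_starts=2, max_iter=50, seed=seed)
        assert a.log_likelihood == b.log_likelihood
        np.testing.assert_array_equal(a.coefficients, b.coefficients)


class TestBIC:
    def test_three_point_closed_form(self):
        z = np.array([0.0, 1.0, 2.0])
        y = np.array([1.0, 2.0, 2.0])
        fit = fit_linear(z, y)
        sigma2 = (1.0 / 6.0) / 3.0  # SSR = 1/6, MLE variance
        ll = -1.5 * (_LOG2PI + np.log(sigma2)) - 1.5
        np.testing.assert_allclose(fit.log_likelihood, ll, atol=1e-10)
        np.testing.assert_allclose(bic(fit), -2 * ll + 3 * np.log(3), atol=1e-10)

    def test_mixture_beats_linear_on_planted_data(self, planted_crossing, crossing_fit):
        z, y, _ = planted_crossing
        assert crossing_fit.bic < bic(fit_linear(z, y))

    def test_parameter_counts(self, crossing_fit, planted_crossing):
        z, y, _ = planted_crossing
        # invert the formula: q = (bic + 2 ll) / ln n
        q_mix = (crossing_fit.bic + 2 * crossing_fit.log_likelihood) / np.log(len(y))
        np.testing.assert_allclose(q_mix, 2 * 3 + 1)  # K(p+2) + K − 1, p=1
        lin = fit_linear(z, y)
        q_lin = (bic(lin) + 2 * lin.log_likelihood) / np.log(len(y))
        np.testing.assert_allclose(q_lin, 3)  # p+2
        # K=1 mixture counts the same parameters as the linear model
        em1 = em_fit(z, y, K=1, n_starts=1, seed=0)
        q1 = (em1.bic + 2 * em1.log_likelihood) / np.log(len(y))
        np.testing.assert_allclose(q1, 3)

    def test_doubling_data_keeps_q(self, planted_crossing):
        z, y, _ = planted_crossing
        z2 = np.vstack([z, z])
        y2 = np.concatenate([y, y])
        fit2 = fit_linear(z2, y2)
        q = (bic(fit2) + 2 * fit2.log_likelihood) / np.log(len(y2))
        np.testing.assert_allclose(q, 3)

    def test_small_n_error(self):
        fit = fit_linear(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        fit.n = 1
        with pytest.raises(ValueError):
            bic(fit)


class TestRelativeEntropy:
    def test_uniform_rows_zero(self):
        assert relative_entropy(np.full((7, 2), 0.5)) == pytest.approx(0.0)

    def test_degenerate_rows_one(self):
        tau = np.zeros((6, 2))
        tau[:3, 0] = 1.0
        tau[3:, 1] = 1.0
        assert relative_entropy(tau) == pytest.approx(1.0)

    def test_nine_tenths_rows(self):
        tau = np.tile([0.9, 0.1], (11, 1))
        expected = 1.0 - (-0.9 * np.log(0.9) - 0.1 * np.log(0.1)) / np.log(2.0)
        assert relative_entropy(tau) == pytest.approx(expected, abs=1e-12)

    def test_invalid_rows(self):
        with pytest.raises(ValueError):
            relative_entropy(np.array([[0.7, 0.7]]))

    def test_permutation_invariance(self, crossing_fit):
        fit = crossing_fit
        perm = MixtureFit(
            K=fit.K,
            coefficients=fit.coefficients[::-1].copy(),
            residual_sds=fit.residual_sds[::-1].copy(),
            mixing_weights=fit.mixing_weights[::-1].copy(),
            posteriors=fit.posteriors[:, ::-1].copy(),
            log_likelihood=fit.log_likelihood,
            bic=fit.bic,
            relative_entropy=fit.relative_entropy,
            n_iterations=fit.n_iterations,
            converged=fit.converged,
            n_starts_used=fit.n_starts_used,
            seed=fit.seed,
            n=fit.n,
        )
        assert bic(perm) == pytest.approx(fit.bic)
        assert relative_entropy(perm.posteriors) == pytest.approx(
            relative_entropy(fit.posteriors)
        )


def _fit_with_slopes(slopes_matrix):
    slopes = np.asarray(slopes_matrix, dtype=float)
    K, p = slopes.shape
    return MixtureFit(
        K=K,
        coefficients=np.column_stack([np.zeros(K), slopes]),
        residual_sds=np.ones(K),
        mixing_weights=np.full(K, 1.0 / K),
        posteriors=np.full((4, K), 1.0 / K),
        log_likelihood=0.0,
        bic=0.0,
        relative_entropy=0.0,
        n_iterations=1,
        converged=True,
        n_starts_used=1,
        seed=0,
        n=4,
    )


class TestInformativeComponent:
    def test_selects_larger_magnitude_column(self):
        # clinical coefficient columns: mean |slope| 0.0473 (I) vs 0.1943 (V)
        fit = _fit_with_slopes([BETA_I_DEFAULT, BETA_V_DEFAULT])
        assert np.mean(np.abs(BETA_I_DEFAULT)) == pytest.approx(0.0473)
        assert np.mean(np.abs(BETA_V_DEFAULT)) == pytest.approx(0.1943)
        assert identify_informative_component(fit) == 1

    def test_identical_components_warns_lowest_index(self):
        fit = _fit_with_slopes([[1.0, -1.0], [1.0, -1.0]])
        with pytest.warns(InformativeTieWarning):
            assert identify_informative_component(fit) == 0

    def test_sign_flip_ties_on_magnitude(self):
        fit = _fit_with_slopes([[1.0, -2.0], [-1.0, 2.0]])
        with pytest.warns(InformativeTieWarning):
            assert identify_informative_component(fit) == 0


class TestModalAssignment:
    def test_argmax(self):
        assert modal_assignment(np.array([[0.7, 0.3]]))[0] == 0
        assert modal_assignment(np.array([[0.3, 0.7]]))[0] == 1

    def test_tie_break_toward_informative(self):
        row = np.array([[0.5, 0.5]])
        assert modal_assignment(row)[0] == 0
        assert modal_assignment(row, informative=1)[0] == 1

    def test_planted_agreement(self, planted_separated, separated_fit):
        _, _, labels = planted_separated
        fit = separated_fit
        k_pos = int(np.argmax(fit.slopes[:, 0]))
        assigned = modal_assignment(fit.posteriors) == k_pos
        agreement = (assigned == labels).mean()
        assert max(agreement, 1.0 - agreement) >= 0.95
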
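import numpy as np
import pytest
import scipy.linalg

import megjoint as mj
from megjoint.eloreta import (
    ConvergenceError,
    apply_inverse,
    elora_inverse_operator,
    elora_weights,
    estimate_snr,
    regularization_from_snr,
)


def test_regularization_from_snr():
    assert regularization_from_snr(2.0) == 0.25
    assert regularization_from_snr(1.0) == 1.0
    assert regularization_from_snr(1e6) == pytest.approx(1e-12)
    with pytest.raises(ValueError):
        regularization_from_snr(0.0)


class TestEstimateSnr:
    times = np.arange(-50.0, 451.0)

    def test_pure_noise_has_unit_snr(self, noise_cov):
        """Whitened pure noise drawn from Sigma gives SNR ~ 1."""
        rng = np.random.default_rng(0)
        chol = scipy.linalg.cholesky(noise_cov, lower=True)
        snrs = [
            estimate_snr(chol @ rng.standard_normal((64, len(self.times))),
                         noise_cov, self.times)
            for _ in range(100)
        ]
        assert np.mean(snrs) == pytest.approx(1.0, abs=0.02)

    def test_homogeneity_and_zero(self, noise_cov):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((64, len(self.times))) * 1e-13
        s1 = estimate_snr(Y, noise_cov, self.times)
        assert estimate_snr(3 * Y, noise_cov, self.times) == pytest.approx(3 * s1)
        assert estimate_snr(np.zeros_like(Y), noise_cov, self.times) == 0.0

    def test_singular_covariance_raises(self):
        Y = np.zeros((4, len(self.times)))
        singular = np.outer(np.ones(4), np.ones(4))
        with pytest.raises(np.linalg.LinAlgError):
            estimate_snr(Y, singular, self.times)

    def test_window_outside_axis_raises(self, noise_cov):
        with pytest.raises(ValueError):
            estimate_snr(np.zeros((64, 10)), noise_cov, np.arange(10.0),
                         window=(0.0, 300.0))


class TestWeights:
    def test_fixed_point_certificate(self, leadfield_ico2, noise_cov):
        w = elora_weights(leadfield_ico2, noise_cov, 0.25, tol=1e-8)
        assert np.all(w.d > 0)
        assert w.residual < 1e-8
        # restarting from the converged weights moves them by < tol
        w2 = elora_weights(leadfield_ico2, noise_cov, 0.25, tol=1e-8)
        assert np.allclose(w.d, w2.d)

    def test_two_by_two_orthogonal_oracle(self):
        """On an orthogonal 2x2 problem the weight fixed point can be
        iterated by hand; the implementation must reproduce it up to the
        trace normalization of the source covariance."""
        L = np.array([[2.0, 0.0], [0.0, 0.5]])
        cov = np.eye(2)

        # independent scratch fixed-point iteration (lambda^2 = 0)
        d = np.ones(2)
        for _ in range(200):
            R = 1.0 / d
            R = R * (2.0 / np.trace(L @ np.diag(R) @ L.T))
            M = np.linalg.inv(L @ np.diag(R) @ L.T)
            d = np.sqrt(np.diag(L.T @ M @ L))
        w = elora_weights(L, cov, 0.0, tol=1e-12, max_iter=500)
        assert np.allclose(w.d, d, rtol=1e-8)

    def test_leadfield_scaling_law(self, leadfield_ico2, noise_cov):
        """L -> cL rescales d by c and the operator by 1/c."""
        c = 3.7
        w1 = elora_weights(leadfield_ico2, noise_cov, 0.25, tol=1e-8)
        w2 = elora_weights(leadfield_ico2.matrix * c, noise_cov, 0.25, tol=1e-8)
        assert np.allclose(w2.d, c * w1.d, rtol=1e-6)
        op1 = elora_inverse_operator(leadfield_ico2, w1, noise_cov, 0.25)
        op2 = elora_inverse_operator(leadfield_ico2.matrix * c, w2, noise_cov, 0.25)
        assert np.allclose(op2.W * c, op1.W, rtol=1e-6)

    def test_non_convergence_carries_history(self, leadfield_ico2, noise_cov):
        with pytest.raises(ConvergenceError) as err:
            elora_weights(leadfield_ico2, noise_cov, 0.25, tol=1e-14, max_iter=2)
        assert len(err.value.history) == 2


class TestInverseOperator:
    def test_exact_localization_all_columns(self, leadfield_ico2, noise_cov):
        """Zero dipole localization error: at lambda^2 = 0, data equal to
        any single leadfield column peaks at that column's vertex."""
        w = elora_weights(leadfield_ico2, noise_cov, 0.0)
        op = elora_inverse_operator(leadfield_ico2, w, noise_cov, 0.0)
        WL = op.W @ leadfield_ico2.matrix
        peaks = np.argmax(np.abs(WL), axis=0)
        assert np.array_equal(peaks, np.arange(leadfield_ico2.shape[1]))

    def test_resolution_matrix_diagonal_dominance(self, leadfield_ico2, noise_cov):
        w = elora_weights(leadfield_ico2, noise_cov, 0.25)
        op = elora_inverse_operator(leadfield_ico2, w, noise_cov, 0.25)
        WL = np.abs(op.W @ leadfield_ico2.matrix)
        # row maxima concentrate on the diagonal for most sources
        frac = np.mean(np.argmax(WL, axis=0) == np.arange(WL.shape[1]))
        assert frac > 0.9

    def test_operator_linearity(self, leadfield_ico2, noise_cov):
        w = elora_weights(leadfield_ico2, noise_cov, 0.25)
        op = elora_inverse_operator(leadfield_ico2, w, noise_cov, 0.25)
        rng = np.random.default_rng(2)
        y1, y2 = rng.standard_normal((2, 64))
        assert np.allclose(op.W @ (y1 + y2), op.W @ y1 + op.W @ y2)


class TestApplyInverse:
    def test_zero_data_zero_estimate(self, leadfield_ico2, noise_cov):
        w = elora_weights(leadfield_ico2, noise_cov, 0.25)
        op = elora_inverse_operator(leadfield_ico2, w, noise_cov, 0.25)
        est = apply_inverse(op, np.zeros((64, 5)))
        assert np.all(est.data == 0) and est.signed

    def test_matches_manual_product_and_time_concat(self, leadfield_ico2, noise_cov):
        w = elora_weights(leadfield_ico2, noise_cov, 0.25)
        op = elora_inverse_operator(leadfield_ico2, w, noise_cov, 0.25)
        rng = np.random.default_rng(4)
        Y = rng.standard_normal((64, 3))
        full = apply_inverse(op, Y).data
        cols = np.column_stack([
            apply_inverse(op, Y[:, [t]]).data.ravel() for t in range(3)
        ])
        assert np.allclose(full, op.W @ Y)
        assert np.allclose(full, cols)

    def test_shape_mismatch_raises(self, leadfield_ico2, noise_cov):
        w = elora_weights(leadfield_ico2, noise_cov, 0.25)
        op = elora_inverse_operator(leadfield_ico2, w, noise_cov, 0.25)
        with pytest.raises(ValueError):
            apply_inverse(op, np.zeros((63, 2)))


def test_model_fit_summary(leadfield_ico2, noise_cov):
    res = mj.Eloreta(leadfield_ico2, noise_cov, snr=2.0).fit()
    assert res.model.lambda2 == 0.25
    text = res.summary()
    assert "lambda^2" in text and "iterations" in text
    est = res.apply(np.zeros(64))
    assert est.n_vertices == leadfield_ico2.shape[1]
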
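"""CS engine: DCT basis, Gaussian measurements, StOMP recovery, quantizer."""

import numpy as np
import pytest
import scipy.fft

from pssahcs import make_operator, reconstruct_block, sense, stomp
from pssahcs.cs import dequantize, quantize
from oracles import exhaustive_1sparse, lstsq_on_support


class TestSensingOperator:
    def test_psi_is_orthonormal(self):
        op = make_operator(8, 16, 0)
        np.testing.assert_allclose(op.psi.T @ op.psi, np.eye(64), atol=1e-10)

    def test_psi_synthesizes_2d_dct_coefficients(self):
        rng = np.random.default_rng(1)
        block = rng.normal(size=(8, 8))
        theta = scipy.fft.dctn(block, norm="ortho").reshape(-1)
        op = make_operator(8, 16, 0)
        np.testing.assert_allclose(op.psi @ theta, block.reshape(-1), atol=1e-10)

    def test_same_seed_bit_identical(self):
        a = make_operator(8, 16, 42)
        b = make_operator(8, 16, 42)
        assert np.array_equal(a.phi, b.phi)

    def test_different_seed_differs(self):
        assert not np.array_equal(
            make_operator(8, 16, 1).phi, make_operator(8, 16, 2).phi
        )

    def test_column_norms_concentrate_near_one(self):
        """Phi entries ~ N(0, 1/m): squared column norms are chi-square
        means, concentrating near 1."""
        op = make_operator(32, 256, 7)
        norms = np.linalg.norm(op.phi, axis=0)
        assert abs(norms.mean() - 1.0) < 0.05

    def test_m_meas_above_block_pixels_rejected(self):
        with pytest.raises(ValueError, match="m_meas"):
            make_operator(4, 17, 0)


class TestSense:
    def test_zero_block_zero_measurements(self):
        op = make_operator(4, 8, 0)
        assert np.all(sense(np.zeros(16), op).y == 0)

    def test_linearity(self):
        op = make_operator(4, 8, 0)
        rng = np.random.default_rng(2)
        x1, x2 = rng.normal(size=16), rng.normal(size=16)
        np.testing.assert_allclose(
            sense(x1 + x2, op).y, sense(x1, op).y + sense(x2, op).y, atol=1e-9
        )

    def test_matches_explicit_matrix_vector_product(self):
        op = make_operator(4, 8, 3)
        rng = np.random.default_rng(3)
        x = rng.normal(size=16)
        want = np.array([float(op.phi[i] @ x) for i in range(8)])
        np.testing.assert_allclose(sense(x, op).y, want, atol=1e-12)

    def test_length_mismatch_raises(self):
        op = make_operator(4, 8, 0)
        with pytest.raises(ValueError, match="pixels"):
            sense(np.zeros(15), op)


class TestStomp:
    def test_zero_measurements_give_zero_vector(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(8, 32))
        assert np.all(stomp(np.zeros(8), A) == 0)

    def test_four_sparse_exact_recovery_rate(self):
        """Noiseless 4-sparse signals at N=64, m=32: exact support and
        sup-norm recovery in >= 95% of 100 seeded trials, and in every
        success the answer matches least squares on the true support."""
        ok = 0
        for trial in range(100):
            op = make_operator(8, 32, trial)
            rng = np.random.default_rng(1000 + trial)
            x = np.zeros(64)
            idx = rng.choice(64, 4, replace=False)
            x[idx] = rng.uniform(1, 3, 4) * rng.choice([-1, 1], 4)
            y = op.A @ x
            xh = stomp(y, op.A)
            if np.linalg.norm(xh - x, np.inf) < 1e-6:
                oracle = lstsq_on_support(y, op.A, idx)
                assert np.linalg.norm(xh - oracle, np.inf) < 1e-6
                ok += 1
        assert ok >= 95

    def test_one_sparse_matches_exhaustive_search(self):
        """At N=8, m=6 the stage threshold must sit below the matched
        filter floor (t=0.5); then StOMP agrees with exhaustive single-atom
        least squares in all 100 trials."""
        for trial in range(100):
            rng = np.random.default_rng(trial)
            A = rng.normal(0, 1 / np.sqrt(6), size=(6, 8))
            x = np.zeros(8)
            x[rng.integers(8)] = rng.uniform(1, 3)
            y = A @ x
            xh = stomp(y, A, t=0.5)
            np.testing.assert_allclose(xh, exhaustive_1sparse(y, A), atol=1e-8)

    def test_residual_norm_nonincreasing_and_stage_bounds(self):
        """Replay the stagewise recursion: residual norms never increase
        and the support never exceeds m."""
        rng = np.random.default_rng(5)
        op = make_operator(8, 24, 9)
        x = scipy.fft.dctn(rng.normal(size=(8, 8)) + 10, norm="ortho").reshape(-1)
        y = op.A @ x
        xh = stomp(y, op.A, t=2.0, max_stages=10)
        assert np.count_nonzero(xh) <= 24
        # recompute the per-stage residuals independently
        support = np.zeros(64, bool)
        r = y.copy()
        norms = [np.linalg.norm(r)]
        for _ in range(10):
            c = op.A.T @ r
            sel = np.abs(c) > 2.0 * np.linalg.norm(r) / np.sqrt(24)
            if not np.any(sel & ~support):
                break
            support |= sel
            if support.sum() > 24:
                keep = np.argsort(np.abs(c) * support)[::-1][:24]
                support = np.zeros(64, bool)
                support[keep] = True
            cols = np.nonzero(support)[0]
            coef, *_ = np.linalg.lstsq(op.A[:, cols], y, rcond=None)
            r = y - op.A[:, cols] @ coef
            norms.append(np.linalg.norm(r))
        assert all(b <= a + 1e-9 for a, b in zip(norms, norms[1:]))

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            stomp(np.ones(4), np.eye(4), t=0.0)


class TestReconstructBlock:
    def test_single_dct_atom_recovered(self):
        op = make_operator(8, 16, 11)
        theta = np.zeros(64)
        theta[5] = 7.0
        block = (op.psi @ theta).reshape(8, 8)
        rec = reconstruct_block(sense(block.reshape(-1), op), op)
        assert np.abs(rec - block).max() < 1e-6

    def test_constant_block_recovered(self):
        op = make_operator(8, 16, 12)
        block = np.full((8, 8), 1234.0)
        rec = reconstruct_block(sense(block.reshape(-1), op), op)
        np.testing.assert_allclose(rec, block, rtol=1e-6)

    def test_smooth_block_small_relative_error_at_half_sampling(self):
        """Smooth synthetic blocks at m/N = 0.5 reconstruct with small
        relative l2 error (bound calibrated once on this configuration —
        mean ~2.4% over seeds — and frozen at 3%)."""
        from pssahcs import ar1_field

        errs = []
        for seed in range(5):
            field = 2048 + 400 * ar1_field(32, 32, 0.97, seed)
            op = make_operator(32, 512, seed)
            rec = reconstruct_block(sense(field.reshape(-1), op), op, t=3.0)
            errs.append(
                np.linalg.norm(rec - field) / np.linalg.norm(field)
            )
        assert np.mean(errs) < 0.03

    def test_deterministic_given_seed_and_params(self):
        op = make_operator(8, 20, 4)
        rng = np.random.default_rng(6)
        block = rng.uniform(0, 4095, size=64)
        a = reconstruct_block(sense(block, op), op)
        b = reconstruct_block(sense(block, op), op)
        assert np.array_equal(a, b)


class TestQuantizer:
    @pytest.mark.parametrize("q_bits", [8, 12])
    def test_round_trip_error_bounded_by_half_step(self, q_bits):
        rng = np.random.default_rng(7)
        v = rng.normal(0, 100, size=(5, 9))
        codes, lo, hi = quantize(v, q_bits)
        back = dequantize(codes, lo, hi, q_bits)
        step = (hi - lo) / (2**q_bits - 1)
        assert np.abs(back - v).max() <= step / 2 + 1e-12

    def test_constant_input_round_trips(self):
        codes, lo, hi = quantize(np.full(6, 3.5), 8)
        assert lo == hi == 3.5
        np.testing.assert_array_equal(dequantize(codes, lo, hi, 8), 3.5)
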
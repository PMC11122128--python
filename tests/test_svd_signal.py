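"""Block-energy SVD signal extraction: oracles, invariants, phenomenology."""

import numpy as np
import pytest

import eyesvd
from eyesvd.svd_signal import (
    BlockGrid,
    SVDResult,
    compute_energy_matrix,
    decompose_energy,
    extract_svd_signal,
    preprocess_signal,
    select_signal_vector,
)
from eyesvd.ts_features import spectral_features

from helpers import naive_energy_matrix, naive_moving_average, naive_svd_pipeline


class TestEnergyMatrix:
    def test_zero_frames_zero_energy(self):
        E = compute_energy_matrix(np.zeros((3, 96, 128)), BlockGrid(6, 8))
        assert np.all(E.E == 0)

    def test_constant_unit_intensity_16x16_blocks(self):
        frames = np.ones((1, 96, 128))
        E = compute_energy_matrix(frames, BlockGrid(6, 8))
        np.testing.assert_allclose(E.E, 256.0)

    def test_uint8_frames_scaled_to_unit_range(self):
        frames = np.full((1, 96, 128), 255, dtype=np.uint8)
        E = compute_energy_matrix(frames, BlockGrid(6, 8))
        np.testing.assert_allclose(E.E, 256.0)

    def test_random_frames_match_nested_loop_oracle(self):
        rng = np.random.default_rng(42)
        frames = rng.integers(0, 255, size=(3, 24, 32)).astype(np.uint8)
        E = compute_energy_matrix(frames, BlockGrid(3, 4))
        np.testing.assert_allclose(E.E, naive_energy_matrix(frames, 3, 4), atol=1e-10)

    def test_indivisible_frame_cropped_to_grid(self):
        frames = np.ones((2, 97, 129))
        E = compute_energy_matrix(frames, BlockGrid(6, 8))
        np.testing.assert_allclose(E.E, 256.0)  # extra row/col cropped

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            compute_energy_matrix(np.empty((0, 96, 128)))

    def test_block_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        E = compute_energy_matrix(rng.random((10, 24, 32)), BlockGrid(3, 4))
        perm = rng.permutation(E.d)
        s1 = np.linalg.svd(E.E, compute_uv=False)
        s2 = np.linalg.svd(E.E[:, perm], compute_uv=False)
        np.testing.assert_allclose(s1, s2, rtol=1e-10)


class TestDecomposeEnergy:
    def test_svd_identities_and_gram_oracle(self):
        rng = np.random.default_rng(7)
        E = rng.random((9, 5))
        res = decompose_energy(E)
        # reconstruction
        rec = res.U @ np.diag(res.S) @ res.V.T
        assert np.linalg.norm(rec - E) <= 1e-8 * np.linalg.norm(E)
        # orthonormal columns, descending singular values
        np.testing.assert_allclose(res.U.T @ res.U, np.eye(res.p), atol=1e-10)
        assert np.all(np.diff(res.S) <= 0)
        # sigma^2 equal eigenvalues of E^T E from an independent eigensolver
        eig = np.sort(np.linalg.eigvalsh(E.T @ E))[::-1]
        np.testing.assert_allclose(res.S**2, eig, rtol=1e-8, atol=1e-10)

    def test_rank_one_matrix(self):
        a, b = np.arange(1.0, 9.0), np.arange(2.0, 7.0)
        res = decompose_energy(np.outer(a, b))
        assert res.S[1] <= 1e-10 * res.S[0]

    def test_non_finite_rejected(self):
        E = np.ones((4, 4))
        E[0, 0] = np.nan
        with pytest.raises(ValueError):
            decompose_energy(E)


def _orthonormal_candidates(k, specs):
    """Build a U whose columns are a constant vector plus the requested
    sinusoids (integer frequencies are mutually orthogonal)."""
    t = np.arange(k)
    cols = [np.ones(k)]
    for kind, cycles in specs:
        if kind == "const":
            cols.append(np.ones(k))
        else:
            cols.append(np.sin(2 * np.pi * cycles * t / k))
    U = np.stack(cols, axis=1)
    U = U / np.linalg.norm(U, axis=0)
    return U


class TestSelectSignalVector:
    def test_pure_sinusoid_candidate_wins(self):
        # u_3 is a 2 Hz sinusoid at 30 FPS (40 cycles over 600 frames)
        U = _orthonormal_candidates(600, [("const", 0), ("sin", 40), ("const", 0)])
        svd = SVDResult(U=U, S=np.array([4.0, 3.0, 2.0, 1.0]), V=np.eye(4))
        rank, _ = select_signal_vector(svd, fps=30.0)
        assert rank == 3

    def test_all_constant_ties_break_to_rank_two(self):
        U = _orthonormal_candidates(600, [("const", 0)] * 3)
        svd = SVDResult(U=U, S=np.array([4.0, 3.0, 2.0, 1.0]), V=np.eye(4))
        rank, _ = select_signal_vector(svd, fps=30.0)
        assert rank == 2

    def test_lower_frequency_in_band_wins_on_equal_shape(self):
        # u_2 at 1 Hz and u_3 at 2 Hz, band [0.5, 15]: smoothing attenuates
        # the higher frequency more, so rank 2 wins
        U = _orthonormal_candidates(600, [("sin", 20), ("sin", 40)])
        svd = SVDResult(U=U, S=np.array([4.0, 3.0, 2.0]), V=np.eye(3))
        rank, _ = select_signal_vector(svd, fps=30.0, band=(0.5, 15.0))
        assert rank == 2

    def test_band_validation(self):
        U = _orthonormal_candidates(64, [("sin", 4)])
        svd = SVDResult(U=U, S=np.array([2.0, 1.0]), V=np.eye(2))
        with pytest.raises(ValueError):
            select_signal_vector(svd, fps=30.0, band=(0.0, 40.0))


class TestPreprocessSignal:
    def test_linear_ramp_identity_window(self):
        v = np.linspace(-1, 1, 11)
        out = preprocess_signal(v, window=1)
        np.testing.assert_allclose(out.values, np.linspace(0, 1, 11), atol=1e-12)

    def test_constant_maps_to_midpoint(self):
        out = preprocess_signal(np.full(10, 3.7), window=3)
        np.testing.assert_allclose(out.values, 0.5)

    def test_alternating_window3_matches_direct_convolution(self):
        v = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        out = preprocess_signal(v, window=3)
        np.testing.assert_allclose(out.values, naive_moving_average(v, 3), atol=1e-12)
        np.testing.assert_allclose(out.values, [0.5, 1 / 3, 2 / 3, 1 / 3, 0.5])

    def test_random_vectors_match_loop_oracle(self):
        rng = np.random.default_rng(3)
        for window in (1, 2, 4, 5, 7):
            v = rng.normal(size=50)
            got = preprocess_signal(v, window=window).values
            exp = naive_moving_average((v - v.min()) / np.ptp(v), window)
            np.testing.assert_allclose(got, exp, atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            preprocess_signal(np.array([0.0, np.inf, 1.0]), window=1)


class TestPipeline:
    def test_small_matrices_match_naive_full_svd_oracle(self):
        """For k, d <= 12 the packaged pipeline (thin SVD, vectorized FFT)
        agrees with an explicit-loop full-SVD reimplementation to 1e-8,
        up to the unidentifiable reflection of the signal."""
        rng = np.random.default_rng(0)
        for k, d in [(8, 5), (12, 12), (10, 3), (5, 12)]:
            E = rng.random((k, d)) + 0.1
            svd = decompose_energy(E)
            rank, vec = select_signal_vector(svd, fps=30.0, window=3)
            sig = preprocess_signal(vec, window=3)
            n_rank, n_sig = naive_svd_pipeline(E, fps=30.0, window=3)
            assert rank == n_rank
            err_direct = np.abs(sig.values - n_sig).max()
            err_reflect = np.abs(sig.values - (1 - n_sig)).max()
            assert min(err_direct, err_reflect) <= 1e-8

    def test_sign_flip_leaves_oscillatory_content_unchanged(self):
        """v -> -v reflects the scaled signal about 1/2: every non-DC FFT
        magnitude (hence all mean-removed spectral content) is preserved."""
        from eyesvd.ts_features import band_power

        rng = np.random.default_rng(9)
        v = rng.normal(size=64)
        a = preprocess_signal(v, window=3).values
        b = preprocess_signal(-v, window=3).values
        np.testing.assert_allclose(b, 1.0 - a, atol=1e-12)
        np.testing.assert_allclose(
            np.abs(np.fft.rfft(a))[1:], np.abs(np.fft.rfft(b))[1:], atol=1e-9
        )
        assert band_power(a, (0.5, 15.0), fps=30.0) == pytest.approx(
            band_power(b, (0.5, 15.0), fps=30.0), rel=1e-9
        )

    def test_intensity_scaling_leaves_signal_unchanged(self):
        rng = np.random.default_rng(4)
        frames = rng.random((20, 24, 32))
        grid = BlockGrid(3, 4)
        E1 = compute_energy_matrix(frames, grid)
        E2 = compute_energy_matrix(frames * 2.0, grid)
        np.testing.assert_allclose(E2.E, 4.0 * E1.E, rtol=1e-12)
        s1 = extract_svd_signal(frames, grid=grid, band=(2.0, 14.0))
        s2 = extract_svd_signal(frames * 2.0, grid=grid, band=(2.0, 14.0))
        assert s1.selected_rank == s2.selected_rank
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-9)

    def test_static_sequence_yields_flat_signal(self, static_sequence):
        frames, _, _, _ = static_sequence
        sig = extract_svd_signal(frames)
        assert np.std(sig.values) <= 1e-6

    def test_two_eye_signal_fusion(self):
        from eyesvd.pipeline import average_signals
        from eyesvd.svd_signal import TemporalSignal

        a = TemporalSignal(np.linspace(0, 1, 10), fps=30.0, source="svd", selected_rank=2)
        b = TemporalSignal(np.linspace(1, 0, 10), fps=30.0, source="svd", selected_rank=3)
        fused = average_signals(a, b)
        np.testing.assert_allclose(fused.values, 0.5)
        with pytest.raises(ValueError):
            average_signals(a, TemporalSignal(np.zeros(10), fps=25.0, source="svd"))

    def test_signal_metadata(self, focus_sequence):
        frames, _, _, _ = focus_sequence
        sig = extract_svd_signal(frames)
        assert sig.source == "svd"
        assert sig.selected_rank is not None and sig.selected_rank >= 2
        assert sig.values.min() >= 0.0 and sig.values.max() <= 1.0
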
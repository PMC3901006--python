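"""Shape model, shape library + PCA basis, noise estimation, design assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vsdikit.model_builder import (
    NoiseSpec,
    ShapeIntervals,
    ShapeParams,
    build_design_matrix,
    default_tau_grid,
    estimate_tau_and_heartbeat,
    generate_shape_library,
    load_design_matrix,
    response_shape,
    save_design_matrix,
    shape_basis,
    shape_time_grid,
    spectral_peaks,
)

REF = ShapeParams(0.1, 0.05, 0.1, 0.2, 0.1, 0.05, 0.3, 0.2)


def durations():
    # segments are either absent or at least 10 ms (sub-frame durations are
    # not resolvable at mesoscopic sampling rates)
    return st.one_of(st.just(0.0), st.floats(0.01, 0.5))


def depths():
    return st.floats(0.0, 1.0, allow_nan=False)


@st.composite
def shape_params(draw):
    a1, a2, a4, a6 = (draw(durations()) for _ in range(4))
    a3 = draw(st.floats(0.01, 0.5))
    a5 = draw(st.floats(0.01, 0.5))
    # a nonzero depth needs its segment to exist for the curve to be continuous
    a7 = draw(depths()) if a2 > 0 else 0.0
    a8 = draw(depths()) if a6 > 0 else 0.0
    return ShapeParams(a1, a2, a3, a4, a5, a6, a7, a8)


class TestResponseShape:
    def test_zero_before_latency(self):
        assert response_shape(np.array([0.05]), REF)[0] == 0.0

    def test_plateau_is_one(self):
        # plateau spans (alpha1+alpha2+alpha3, +alpha4] = (0.25, 0.45]
        assert response_shape(np.array([0.3]), REF)[0] == 1.0

    def test_branch_endpoints_reach_depths(self):
        """Dip endpoint hits -alpha7; decay endpoint hits -alpha8 (closed forms)."""
        t_dip_end = REF.alpha1 + REF.alpha2
        t_fall_end = (REF.alpha1 + REF.alpha2 + REF.alpha3
                      + REF.alpha4 + REF.alpha5)
        vals = response_shape(np.array([t_dip_end, t_fall_end]), REF)
        assert vals[0] == pytest.approx(-REF.alpha7, abs=1e-12)
        assert vals[1] == pytest.approx(-REF.alpha8, abs=1e-12)

    def test_reduces_to_raised_cosine_trapezoid(self):
        p = ShapeParams(0.1, 0.0, 0.2, 0.3, 0.2, 0.0, 0.0, 0.0)
        t = np.linspace(0, 1.2, 2401)
        r = response_shape(t, p)
        assert r.max() == pytest.approx(1.0, abs=1e-9)
        assert r.min() == pytest.approx(0.0, abs=1e-12)
        plateau = (t > 0.3 + 1e-9) & (t <= 0.6 + 1e-9)
        np.testing.assert_allclose(r[plateau], 1.0, atol=1e-9)

    def test_zero_outside_support(self):
        t = np.linspace(-0.5, 2.0, 1001)
        r = response_shape(t, REF)
        outside = (t <= REF.alpha1) | (t > REF.support_end + 1e-12)
        np.testing.assert_array_equal(r[outside], 0.0)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(shape_params())
    def test_continuity_and_range(self, p):
        """r is continuous at every breakpoint and bounded by [-max depth, 1]."""
        breaks = np.cumsum([p.alpha1, p.alpha2, p.alpha3,
                            p.alpha4, p.alpha5, p.alpha6])
        eps = 1e-12
        left = response_shape(breaks - eps, p)
        right = response_shape(breaks + eps, p)
        # a continuous function changes negligibly across a 2e-12 gap
        assert np.max(np.abs(left - right)) < 1e-9
        t = np.linspace(-0.1, p.support_end + 0.1, 2000)
        r = response_shape(t, p)
        assert r.max() <= 1.0 + 1e-12
        assert r.min() >= -max(p.alpha7, p.alpha8) - 1e-12

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            ShapeParams(alpha3=-0.1)
        with pytest.raises(ValueError):
            ShapeParams(alpha7=1.5)


class TestShapeLibrary:
    def test_single_combination_uses_midpoints(self):
        iv = ShapeIntervals(
            alpha1=(0.0, 0.2, 1), alpha2=(0.0, 0.0, 1), alpha3=(0.1, 0.3, 1),
            alpha4=(0.2, 0.2, 1), alpha5=(0.1, 0.1, 1), alpha6=(0.0, 0.0, 1),
            alpha7=(0.0, 0.0, 1), alpha8=(0.0, 0.4, 1))
        t = np.linspace(0, 2, 200)
        lib = generate_shape_library(iv, t)
        assert lib.shape == (1, 200)
        mid = ShapeParams(0.1, 0.0, 0.2, 0.2, 0.1, 0.0, 0.0, 0.2)
        np.testing.assert_allclose(lib[0], response_shape(t, mid))

    def test_two_step_sweep_varies_only_plateau(self):
        iv = ShapeIntervals(
            alpha1=(0.1, 0.1, 1), alpha2=(0.0, 0.0, 1), alpha3=(0.2, 0.2, 1),
            alpha4=(0.1, 0.5, 2), alpha5=(0.2, 0.2, 1), alpha6=(0.0, 0.0, 1),
            alpha7=(0.0, 0.0, 1), alpha8=(0.0, 0.0, 1))
        t = np.linspace(0, 2, 400)
        lib = generate_shape_library(iv, t)
        assert lib.shape[0] == 2
        # both rise identically; the longer plateau stays at 1 longer
        rise = t <= 0.3
        np.testing.assert_allclose(lib[0][rise], lib[1][rise])
        assert (lib[1] == 1.0).sum() > (lib[0] == 1.0).sum()

    def test_full_sweep_count_matches_combinatorics(self):
        iv = ShapeIntervals(
            alpha1=(0.0, 0.1, 3), alpha2=(0.0, 0.1, 3), alpha3=(0.0, 0.2, 3),
            alpha4=(0.0, 0.2, 3), alpha5=(0.0, 0.2, 3), alpha6=(0.0, 0.1, 3),
            alpha7=(0.0, 0.5, 3), alpha8=(0.0, 0.5, 3))
        assert iv.grid_size == 3**8
        t = np.linspace(0, 1.5, 150)
        lib = generate_shape_library(iv, t)
        # independent count of degenerate (all-zero) combinations
        import itertools
        n_zero = 0
        for combo in itertools.product(*iv.grids()):
            if not np.any(response_shape(t, ShapeParams(*combo)) != 0.0):
                n_zero += 1
        assert lib.shape[0] == 3**8 - n_zero
        assert n_zero > 0  # the sweep includes zero-duration degenerates

    def test_cap_enforced(self):
        iv = ShapeIntervals(cap=10)
        with pytest.raises(ValueError, match="cap"):
            generate_shape_library(iv, np.linspace(0, 1, 50))


class TestShapeBasis:
    def test_single_shape_normalised(self):
        t = np.linspace(0, 1, 100)
        row = response_shape(t, ShapeParams(0.1, 0, 0.2, 0.2, 0.2, 0, 0, 0))
        basis = shape_basis(row[None, :], L=1)
        np.testing.assert_allclose(basis[:, 0], row / np.linalg.norm(row),
                                   atol=1e-12)

    def test_orthonormal_columns(self):
        rng = np.random.default_rng(0)
        lib = rng.normal(size=(40, 60))
        B = shape_basis(lib, L=5)
        np.testing.assert_allclose(B.T @ B, np.eye(5), atol=1e-10)

    def test_reconstruction_error_equals_tail_singular_energy(self):
        """Residual energy after projecting onto L components equals the
        SVD tail energy, and is non-increasing in L (optimality oracle)."""
        rng = np.random.default_rng(1)
        lib = rng.normal(size=(100, 50))
        sv = np.linalg.svd(lib, compute_uv=False)
        prev = np.inf
        for L in (1, 3, 10, 30, 50):
            B = shape_basis(lib, L=L)
            resid = lib - (lib @ B) @ B.T
            energy = np.sum(resid**2)
            assert energy == pytest.approx(np.sum(sv[L:] ** 2), rel=1e-8)
            assert energy <= prev + 1e-9
            prev = energy

    def test_orthogonal_library_spanned_exactly(self):
        lib = np.eye(4, 20) * np.array([[4.0], [3.0], [2.0], [1.0]])
        B = shape_basis(lib, L=4)
        resid = lib - (lib @ B) @ B.T
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_l_out_of_range(self):
        with pytest.raises(ValueError):
            shape_basis(np.ones((3, 10)), L=0)
        with pytest.raises(ValueError):
            shape_basis(np.ones((3, 10)), L=4)


class TestNoiseEstimation:
    def test_noiseless_exponential_recovers_grid_tau(self):
        t = np.arange(200) / 100.0
        y = 3.0 + 0.5 * np.exp(-t / 2.0) + 1e-3 * np.sin(2 * np.pi * 3.0 * t)
        grid = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        tau, f = estimate_tau_and_heartbeat(y, 100.0, tau_grid=grid)
        assert tau == 2.0
        assert f == pytest.approx(3.0, abs=100.0 / 200)

    def test_sinusoid_frequency_within_one_bin(self):
        fs, T = 110.0, 220
        t = np.arange(T) / fs
        y = np.sin(2 * np.pi * 2.5 * t)
        _, f = estimate_tau_and_heartbeat(y, fs, heart_band=(1.0, 15.0))
        # independent oracle: argmax of the periodogram
        from scipy.signal import periodogram
        freqs, pxx = periodogram(y, fs=fs)
        expected = freqs[np.argmax(pxx)]
        assert f == pytest.approx(expected, abs=1e-9)
        assert abs(f - 2.5) <= fs / T

    def test_constant_timecourse_flagged(self):
        with pytest.raises(ValueError, match="no oscillation"):
            estimate_tau_and_heartbeat(np.full(64, 5.0), 100.0)

    def test_empty_band_raises(self):
        y = np.sin(np.arange(64))
        with pytest.raises(ValueError, match="band"):
            estimate_tau_and_heartbeat(y, 100.0, heart_band=(60.0, 80.0))

    def test_default_grid_spans_trial_duration(self):
        g = default_tau_grid(2.0)
        assert g[0] == pytest.approx(0.2)
        assert g[-1] == pytest.approx(20.0)
        assert len(g) == 50


class TestSpectralPeaks:
    def test_white_noise_rarely_yields_peaks(self):
        """At z=8 white noise should produce an empty list >= 95/100 runs."""
        empty = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(256)
            if not spectral_peaks(y, 100.0, z_threshold=8.0):
                empty += 1
        assert empty >= 95

    def test_two_sinusoids_recovered(self):
        fs, T = 100.0, 1000
        t = np.arange(T) / fs
        rng = np.random.default_rng(2)
        y = (np.sin(2 * np.pi * 2.5 * t) + 0.8 * np.sin(2 * np.pi * 7.3 * t)
             + 0.01 * rng.standard_normal(T))
        peaks = spectral_peaks(y, fs, z_threshold=8.0)
        bin_w = fs / T
        assert any(abs(p - 2.5) <= bin_w for p in peaks)
        assert any(abs(p - 7.3) <= bin_w for p in peaks)
        # sorted by descending amplitude: 2.5 Hz dominates
        assert abs(peaks[0] - 2.5) <= bin_w

    def test_total_exclusion_gives_empty_list(self):
        t = np.arange(256) / 100.0
        y = np.sin(2 * np.pi * 5.0 * t)
        assert spectral_peaks(y, 100.0, exclude_bands=[(0.0, 50.0)]) == []


class TestDesignMatrix:
    def test_constant_only(self):
        dm = build_design_matrix(50, 100.0, 10)
        assert dm.X.shape == (50, 1)
        np.testing.assert_array_equal(dm.X[:, 0], 1.0)
        assert list(dm.constant_idx) == [0]
        assert dm.noise_idx.size == 0 and dm.signal_idx.size == 0

    def test_column_count_and_order(self):
        noise = NoiseSpec(include_exponential=True, tau=5.0,
                          oscillation_freqs=(2.0,), n_harmonics=1)
        basis = np.linalg.qr(
            np.random.default_rng(0).normal(size=(50, 3)))[0]
        dm = build_design_matrix(50, 100.0, 10, noise=noise,
                                 shape_basis_matrix=basis)
        assert dm.n_regressors == 1 + 1 + 2 + 3
        assert dm.labels[:4] == ["constant", "bleach_exp",
                                 "heart_sin_h1", "heart_cos_h1"]
        assert dm.labels[4:] == ["shape_pc1", "shape_pc2", "shape_pc3"]
        assert list(dm.noise_idx) == [1, 2, 3]
        assert list(dm.signal_idx) == [4, 5, 6]

    def test_duplicate_frequency_rank_deficient(self):
        noise = NoiseSpec(include_exponential=False,
                          oscillation_freqs=(2.0, 2.0), n_harmonics=1)
        with pytest.raises(ValueError, match="rank deficient"):
            build_design_matrix(100, 100.0, 10, noise=noise)

    def test_harmonic_above_nyquist_rejected(self):
        noise = NoiseSpec(include_exponential=False,
                          oscillation_freqs=(30.0,), n_harmonics=2)
        with pytest.raises(ValueError, match="Nyquist"):
            build_design_matrix(100, 100.0, 10, noise=noise)

    def test_shape_grid_zero_before_onset(self):
        t = shape_time_grid(100, 100.0, 20)
        lib = generate_shape_library(ShapeIntervals(), t)
        assert np.all(lib[:, :21] == 0.0)

    def test_save_load_roundtrip(self, tmp_path):
        noise = NoiseSpec(tau=2.0, oscillation_freqs=(2.5,), n_harmonics=2)
        dm = build_design_matrix(60, 110.0, 12, noise=noise)
        save_design_matrix(dm, tmp_path / "design")
        back = load_design_matrix(tmp_path / "design")
        np.testing.assert_allclose(back.X, dm.X, rtol=1e-10)
        assert back.labels == dm.labels
        np.testing.assert_array_equal(back.noise_idx, dm.noise_idx)
        assert back.sampling_rate == dm.sampling_rate
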
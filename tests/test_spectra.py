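import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from irmix import (
    RawSpectrum,
    Spectrum,
    WavenumberGrid,
    avg_cdf_difference,
    cdf,
    mean_wavenumber,
    preprocess,
    regrid,
    spectral_mse,
)
from irmix.exceptions import (
    DegenerateSpectrumError,
    IncompatibleGridsError,
    InvalidInputError,
    NotNormalizedError,
)

from conftest import gaussian_spectrum


class TestGrid:
    def test_default_covers_0_to_4996(self, grid):
        assert grid.wavenumbers[0] == 0.0
        assert grid.wavenumbers[-1] == 4996.0
        assert grid.n_points == 1250
        assert grid.span == 5000.0

    @pytest.mark.parametrize("kwargs", [{"step": 0.0}, {"step": -1.0}, {"n_points": 1}])
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(InvalidInputError):
            WavenumberGrid(**kwargs)


class TestRegrid:
    def test_points_already_on_grid_pass_through(self, small_grid):
        w = small_grid.wavenumbers
        x = np.arange(small_grid.n_points, dtype=float)
        out = regrid(RawSpectrum(w, x), small_grid)
        np.testing.assert_array_equal(out.intensities, x)

    def test_hand_linear_interpolation(self, small_grid):
        raw = RawSpectrum(np.array([0.0, 8.0]), np.array([0.0, 2.0]))
        out = regrid(raw, small_grid)
        np.testing.assert_allclose(out.intensities[:4], [0.0, 1.0, 2.0, 0.0])
        assert not out.intensities[3:].any()

    def test_outside_support_is_zero(self, grid):
        raw = RawSpectrum(np.array([2000.0, 2500.0, 3000.0]), np.array([1.0, 2.0, 1.0]))
        out = regrid(raw, grid)
        nu = grid.wavenumbers
        assert not out.intensities[nu < 2000.0].any()
        assert not out.intensities[nu > 3000.0].any()
        assert out.intensities[(nu >= 2000.0) & (nu <= 3000.0)].all()

    def test_single_point_rejected(self):
        with pytest.raises(InvalidInputError):
            RawSpectrum(np.array([1.0]), np.array([1.0]))

    def test_non_increasing_wavenumbers_rejected(self):
        with pytest.raises(InvalidInputError):
            RawSpectrum(np.array([0.0, 8.0, 8.0]), np.array([1.0, 1.0, 1.0]))

    def test_regrid_roundtrip_mse_zero(self, small_grid):
        s = gaussian_spectrum(small_grid, center=30.0, sigma=8.0)
        back = regrid(RawSpectrum(s.wavenumbers, s.intensities), small_grid)
        assert spectral_mse(s, Spectrum(small_grid, back.intensities, True)) == 0.0


class TestPreprocess:
    def test_identity_on_clean_unit_area_input(self, small_grid):
        s = gaussian_spectrum(small_grid, center=30.0, sigma=8.0)
        out = preprocess(s, smooth_sigma=0.0)
        np.testing.assert_allclose(out.intensities, s.intensities, atol=1e-15)
        assert out.normalized

    def test_smoothing_conserves_mass(self, grid):
        x = np.zeros(grid.n_points)
        x[300] = 5.0
        out = preprocess(Spectrum(grid, x), smooth_sigma=8.0, normalize=False)
        assert out.intensities.sum() == pytest.approx(5.0, abs=1e-9)
        assert np.count_nonzero(out.intensities > 1e-12) > 1

    def test_clipping_before_normalization(self, small_grid):
        x = np.zeros(small_grid.n_points)
        x[0], x[1] = -1.0, 2.0
        out = preprocess(Spectrum(small_grid, x), clip=True, normalize=False)
        np.testing.assert_array_equal(out.intensities[:2], [0.0, 2.0])

    def test_all_zero_after_clip_is_degenerate(self, small_grid):
        x = -np.ones(small_grid.n_points)
        with pytest.raises(DegenerateSpectrumError):
            preprocess(Spectrum(small_grid, x), clip=True, normalize=True)

    def test_idempotence(self, grid):
        rng = np.random.default_rng(0)
        raw = Spectrum(grid, rng.normal(size=grid.n_points))
        once = preprocess(raw, smooth_sigma=8.0)
        twice = preprocess(once, smooth_sigma=0.0)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(
        hnp.arrays(
            float,
            64,
            elements=st.floats(-1.0, 10.0, allow_nan=False),
        ).filter(lambda x: np.maximum(x, 0).sum() > 1e-6)
    )
    def test_output_always_nonneg_unit_area(self, x):
        g = WavenumberGrid(0.0, 4.0, 64)
        out = preprocess(Spectrum(g, x), smooth_sigma=8.0)
        assert (out.intensities >= 0).all()
        assert out.area == pytest.approx(1.0, abs=1e-9)


class TestMse:
    def test_self_distance_zero(self, small_grid):
        s = gaussian_spectrum(small_grid, 30.0)
        assert spectral_mse(s, s) == 0.0

    def test_hand_value(self):
        g = WavenumberGrid(0.0, 1.0, 3)
        a = Spectrum(g, np.array([0.0, 1.0, 0.0]))
        b = Spectrum(g, np.array([0.0, 0.0, 1.0]))
        assert spectral_mse(a, b) == pytest.approx(2.0 / 3.0)
        assert spectral_mse(b, a) == spectral_mse(a, b)

    def test_grid_mismatch(self, small_grid, grid):
        a = gaussian_spectrum(small_grid, 30.0)
        b = gaussian_spectrum(grid, 30.0)
        with pytest.raises(IncompatibleGridsError):
            spectral_mse(a, b)


class TestCdf:
    def test_uniform_spectrum_is_linear_ramp(self, small_grid):
        n, step = small_grid.n_points, small_grid.step
        s = Spectrum(small_grid, np.full(n, 1.0 / (n * step)), normalized=True)
        c = cdf(s)
        np.testing.assert_allclose(c, np.arange(1, n + 1) / n, atol=1e-12)
        assert c[-1] == pytest.approx(1.0, abs=1e-9)

    def test_all_mass_at_first_point(self, small_grid):
        x = np.zeros(small_grid.n_points)
        x[0] = 1.0 / small_grid.step
        c = cdf(Spectrum(small_grid, x, normalized=True))
        np.testing.assert_allclose(c, 1.0, atol=1e-12)

    def test_unnormalized_rejected(self, small_grid):
        with pytest.raises(NotNormalizedError):
            cdf(Spectrum(small_grid, np.ones(small_grid.n_points)))

    @settings(max_examples=50, derandomize=True)
    @given(
        hnp.arrays(float, 32, elements=st.floats(0.0, 10.0)).filter(
            lambda x: x.sum() > 1e-6
        )
    )
    def test_monotone_nondecreasing_ending_at_one(self, x):
        g = WavenumberGrid(0.0, 2.0, 32)
        s = Spectrum(g, x / (x.sum() * g.step), normalized=True)
        c = cdf(s)
        assert (np.diff(c) >= -1e-12).all()
        assert c[-1] == pytest.approx(1.0, abs=1e-9)


class TestAvgCdfDifference:
    def test_identity_zero(self, grid):
        s = gaussian_spectrum(grid, 1500.0)
        assert avg_cdf_difference(s, s) == 0.0

    @pytest.mark.parametrize("delta", [4.0, 8.0, 20.0])
    def test_rigid_shift_identity(self, grid, delta):
        """Signed mean CDF gap of a rigid up-shift equals shift / span."""
        a = gaussian_spectrum(grid, 1500.0, sigma=30.0)
        bins = int(delta / grid.step)
        x = np.zeros_like(a.intensities)
        x[bins:] = a.intensities[:-bins]
        b = Spectrum(grid, x / (x.sum() * grid.step), normalized=True)
        assert avg_cdf_difference(a, b, signed=True) == pytest.approx(
            delta / grid.span, rel=1e-6
        )

    def test_antisymmetry(self, grid):
        a = gaussian_spectrum(grid, 1000.0)
        b = gaussian_spectrum(grid, 2400.0)
        assert avg_cdf_difference(a, b) == pytest.approx(-avg_cdf_difference(b, a))
        assert avg_cdf_difference(a, b, signed=False) >= abs(avg_cdf_difference(a, b))

    def test_sign_convention_red_shift_positive(self, grid):
        red = gaussian_spectrum(grid, 800.0)
        blue = gaussian_spectrum(grid, 2000.0)
        assert avg_cdf_difference(red, blue) > 0

    def test_first_moment_identity(self, grid):
        """signed gap * span == mean_wavenumber(b) - mean_wavenumber(a)."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            xa, xb = rng.random(grid.n_points), rng.random(grid.n_points)
            a = Spectrum(grid, xa / (xa.sum() * grid.step), normalized=True)
            b = Spectrum(grid, xb / (xb.sum() * grid.step), normalized=True)
            lhs = avg_cdf_difference(a, b) * grid.span
            rhs = mean_wavenumber(b) - mean_wavenumber(a)
            # discretization: CDF treats each bin as right-closed, off by <= one step
            assert lhs == pytest.approx(rhs, abs=grid.step)
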
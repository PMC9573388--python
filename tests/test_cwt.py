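import numpy as np
import pytest
import pywt

from ecgfusion.cwt import (
    CwtResult,
    ScaleGrid,
    ScalogramTransformer,
    SUPPORTED_WAVELETS,
    compute_cwt,
    get_wavelet,
    make_scales,
    make_scalogram,
    scale_to_frequency,
)


def quadrature_oracle(x, a, psi):
    """Direct trapezoid quadrature of the CWT integral, one scale."""
    n = len(x)
    t = np.arange(n)
    out = np.empty(n)
    for b in range(n):
        out[b] = np.trapezoid(x * psi((t - b) / a)) / np.sqrt(a)
    return out


class TestScales:
    def test_default_grid_spans_2p16_to_216_with_100_values(self):
        grid = make_scales()
        assert grid.n == 100
        assert grid.lo == pytest.approx(2.16)
        assert grid.hi == pytest.approx(216.0)

    def test_two_point_grid(self):
        np.testing.assert_allclose(make_scales(2, 1.0, 2.0).scales, [1.0, 2.0])

    def test_linear_spacing(self):
        grid = make_scales()
        np.testing.assert_allclose(np.diff(grid.scales), (216 - 2.16) / 99)

    def test_nonpositive_lo_rejected(self):
        with pytest.raises(ValueError):
            make_scales(lo=0.0)

    def test_unordered_scales_rejected(self):
        with pytest.raises(ValueError):
            ScaleGrid(np.array([2.0, 1.0]))


class TestScaleToFrequency:
    def test_unit_fc_example(self):
        w = get_wavelet("mexh")
        spec = type(w)(name="unit", psi=w.psi, fc=1.0)
        assert scale_to_frequency(36.0, spec, 360.0) == pytest.approx(10.0)

    def test_inverse_proportionality(self):
        w = get_wavelet("gaus8")
        assert scale_to_frequency(20.0, w, 360.0) == pytest.approx(
            2 * scale_to_frequency(40.0, w, 360.0)
        )

    def test_half_fc_example(self):
        w = get_wavelet("mexh")
        spec = type(w)(name="half", psi=w.psi, fc=0.5)
        assert scale_to_frequency(2.16, spec, 360.0) == pytest.approx(
            83.33, abs=0.01
        )

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            scale_to_frequency(0.0, get_wavelet("mexh"), 360.0)


class TestWaveletRegistry:
    def test_unknown_wavelet_error_lists_supported_names(self):
        with pytest.raises(ValueError, match="gaus8.*gaus4.*mexh.*morl"):
            get_wavelet("db4")

    @pytest.mark.parametrize("name", SUPPORTED_WAVELETS)
    def test_center_frequency_agrees_with_pywt(self, name):
        # both estimators locate a quantized spectral peak; agreement is
        # to ~10%, not exact
        ours = get_wavelet(name).fc
        ref = pywt.central_frequency(name)
        assert ours == pytest.approx(ref, rel=0.15)

    @pytest.mark.parametrize("name", SUPPORTED_WAVELETS)
    def test_shape_matches_pywt_definition(self, name):
        # correlation of sampled wavelets is ~1 up to sign/normalization
        psi_ref, t = pywt.ContinuousWavelet(name).wavefun(10)
        ours = get_wavelet(name).psi(np.asarray(t))
        r = np.corrcoef(np.real(psi_ref), ours)[0, 1]
        assert abs(r) > 0.999


class TestComputeCwt:
    @pytest.mark.parametrize("name", SUPPORTED_WAVELETS)
    def test_single_scale_matches_quadrature_oracle(self, name):
        x = np.sin(2 * np.pi * 5 * np.arange(50) / 50)
        w = get_wavelet(name)
        res = compute_cwt(x, ScaleGrid(np.array([8.0])), w, fs=360.0)
        ref = quadrature_oracle(x, 8.0, w.psi)
        rel = np.abs(res.coefficients[0] - ref).max() / np.abs(ref).max()
        assert rel < 1e-6

    @pytest.mark.parametrize("name", SUPPORTED_WAVELETS)
    def test_oracle_agreement_on_random_signal_many_scales(self, name, rng):
        x = rng.standard_normal(60)
        grid = ScaleGrid(np.array([2.16, 7.0, 31.0]))
        w = get_wavelet(name)
        res = compute_cwt(x, grid, w, fs=360.0)
        for i, a in enumerate(grid.scales):
            ref = quadrature_oracle(x, a, w.psi)
            rel = np.abs(res.coefficients[i] - ref).max() / np.abs(ref).max()
            assert rel < 1e-6

    @pytest.mark.parametrize("name", SUPPORTED_WAVELETS)
    def test_zero_signal_annihilation(self, name):
        res = compute_cwt(np.zeros(40), make_scales(5, 2.0, 20.0), name)
        np.testing.assert_array_equal(res.coefficients, 0.0)

    @pytest.mark.parametrize("name", SUPPORTED_WAVELETS)
    def test_linearity(self, name, rng):
        x = rng.standard_normal(40)
        grid = make_scales(5, 2.0, 20.0)
        c1 = compute_cwt(x, grid, name).coefficients
        c2 = compute_cwt(2.0 * x, grid, name).coefficients
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-12, atol=1e-12)

    def test_frequency_axis_monotone_decreasing_in_scale(self):
        res = compute_cwt(np.random.default_rng(0).standard_normal(50))
        assert np.all(np.diff(res.frequencies) < 0)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            compute_cwt(np.array([1.0]))


class TestScalogram:
    def test_shape_is_100_by_100_by_default(self, rng):
        res = compute_cwt(rng.standard_normal(200))
        sg = make_scalogram(res)
        assert sg.values.shape == (100, 100)

    def test_values_within_unit_interval(self, rng):
        for _ in range(3):
            res = compute_cwt(rng.standard_normal(73), make_scales(30, 2.0, 50.0))
            sg = make_scalogram(res, out_shape=(100, 100))
            assert sg.values.min() >= 0.0 and sg.values.max() <= 1.0

    def test_zero_coefficients_give_zero_image(self):
        res = compute_cwt(np.zeros(50), make_scales(10, 2.0, 20.0))
        np.testing.assert_array_equal(make_scalogram(res).values, 0.0)

    def test_constant_magnitude_gives_zero_image(self):
        grid = make_scales(10, 2.0, 20.0)
        res = CwtResult(np.full((10, 50), 3.0), grid,
                        np.linspace(10, 1, 10), "mexh")
        np.testing.assert_array_equal(make_scalogram(res).values, 0.0)

    def test_degenerate_single_row_rejected(self):
        res = CwtResult(np.ones((1, 50)), ScaleGrid(np.array([2.0])),
                        np.array([1.0]), "mexh")
        with pytest.raises(ValueError):
            make_scalogram(res)


class TestScalogramTransformer:
    def test_sklearn_roundtrip_shapes(self, rng):
        X = rng.standard_normal((4, 40))
        tf = ScalogramTransformer(n_scales=20, out_shape=(16, 16))
        out = tf.fit_transform(X)
        assert out.shape == (4, 256)
        assert tf.image_shape_ == (16, 16)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_get_params_roundtrip(self):
        tf = ScalogramTransformer(wavelet="mexh")
        params = tf.get_params()
        assert params["wavelet"] == "mexh"
        tf.set_params(wavelet="morl")
        assert tf.wavelet == "morl"
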
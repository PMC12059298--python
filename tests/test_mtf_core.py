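import dataclasses

import numpy as np
import pytest
from scipy.special import erf

from ctseqmtf import (
    DegenerateLSFError,
    ESFCurve,
    LSFCurve,
    MeasurementConfig,
    MTFCurve,
    MTFFitParams,
    PhantomSpec,
    ResolutionBeyondNyquistError,
    compute_esf,
    esf_to_lsf,
    fit_mtf_model,
    gaussian_f10,
    gaussian_f50,
    generate_sequence,
    locate_edge_roi,
    lsf_to_mtf,
    measure_sequence,
    pool_sequence_esf,
    resolution_metrics,
    upsample_esf,
)
from ctseqmtf.edge_localization import EdgeCenter, EdgeROI
from ctseqmtf.mtf_core import finalize_lsf


def phi(x):
    return 0.5 * (1.0 + erf(x / np.sqrt(2.0)))


def erf_esf(sigma_mm, spacing=0.5, n=41, center_offset_px=0.0, noise=None):
    pos = np.arange(n) * spacing
    edge = (n // 2 + center_offset_px) * spacing
    vals = -1000.0 + 1120.0 * phi((pos - edge) / sigma_mm)
    if noise is not None:
        vals = vals + noise
    return ESFCurve(positions_mm=pos, values_hu=vals)


def make_roi(patch, spacing=0.5):
    center = EdgeCenter(x_c=100, y_c=100, centroid=(100.0, 120.0))
    return EdgeROI(patch=patch, center=center, pixel_spacing_mm=spacing)


class TestComputeESF:
    def test_constant_patch(self):
        esf = compute_esf(make_roi(np.full((41, 41), 100.0)))
        assert len(esf) == 41
        np.testing.assert_array_equal(esf.values_hu, 100.0)

    def test_row_index_patch(self):
        patch = np.tile(np.arange(41.0)[:, None], (1, 41))
        esf = compute_esf(make_roi(patch))
        np.testing.assert_allclose(esf.values_hu, np.arange(41.0))
        np.testing.assert_allclose(esf.positions_mm, np.arange(41) * 0.5)

    def test_matches_single_column_on_column_constant_edge(self):
        """For a noiseless edge constant along columns, the column average
        equals any single column's profile."""
        profile = -1000.0 + 1120.0 * phi((np.arange(41) - 20) / 1.2)
        patch = np.tile(profile[:, None], (1, 41))
        esf = compute_esf(make_roi(patch))
        np.testing.assert_allclose(esf.values_hu, patch[:, 7])


class TestUpsampleESF:
    def test_five_fold_gives_201_samples(self):
        up = upsample_esf(erf_esf(0.5), factor=5)
        assert len(up) == 201
        assert up.spacing_mm == pytest.approx(0.1)

    def test_original_samples_reproduced(self):
        esf = erf_esf(0.5)
        up = upsample_esf(esf, factor=5)
        np.testing.assert_allclose(up.values_hu[::5], esf.values_hu, atol=1e-9)

    def test_linear_ramp_is_exact_everywhere(self):
        esf = ESFCurve(positions_mm=np.arange(10) * 0.5,
                       values_hu=3.0 * np.arange(10) + 7.0)
        up = upsample_esf(esf, factor=4)
        np.testing.assert_allclose(up.values_hu, 3.0 * up.positions_mm / 0.5 + 7.0,
                                   atol=1e-9)

    def test_bad_factor(self):
        with pytest.raises(ValueError, match="factor"):
            upsample_esf(erf_esf(0.5), factor=0)


class TestPoolSequenceESF:
    def test_identical_noiseless_curves_pool_to_themselves(self):
        esf = erf_esf(0.5)
        pooled = pool_sequence_esf([esf] * 20, smoothing="auto")
        assert not pooled.degenerate
        np.testing.assert_allclose(pooled.smooth_curve.values_hu[::5],
                                   esf.values_hu, atol=1e-6)

    def test_scatter_size_counts_every_sample(self):
        pooled = pool_sequence_esf([erf_esf(0.5)] * 20)
        assert pooled.scatter_positions_mm.size == 20 * 41

    def test_single_curve_degenerates_with_flag(self):
        pooled = pool_sequence_esf([erf_esf(0.5)])
        assert pooled.degenerate
        assert pooled.smoothing_parameter == 1.0

    def test_mismatched_grids_rejected(self):
        a = erf_esf(0.5, spacing=0.5)
        b = erf_esf(0.5, spacing=0.6)
        with pytest.raises(ValueError, match="mismatched"):
            pool_sequence_esf([a, b])

    def test_pooling_beats_single_noisy_curves(self):
        """Smoothing-spline pooling of 20 noisy edge profiles tracks the true
        profile better than the average single profile does (seed 42)."""
        rng = np.random.default_rng(42)
        truth = erf_esf(0.5)
        noisy = [erf_esf(0.5, noise=rng.normal(0, 15, 41)) for _ in range(20)]
        pooled = pool_sequence_esf(noisy, smoothing="auto")
        pooled_rmse = np.sqrt(np.mean(
            (pooled.smooth_curve.values_hu[::5] - truth.values_hu) ** 2))
        slice_rmse = np.mean([
            np.sqrt(np.mean((c.values_hu - truth.values_hu) ** 2)) for c in noisy])
        assert pooled_rmse < slice_rmse

    def test_explicit_smoothing_parameter_validated(self):
        with pytest.raises(ValueError, match="smoothing parameter"):
            pool_sequence_esf([erf_esf(0.5)] * 2, smoothing=1.5)


class TestLSF:
    def test_finalize_matches_worked_example(self):
        raw = np.array([0, 0, 0, 0, 0, 2, 4, 2, 0], dtype=float)
        out = finalize_lsf(raw)
        np.testing.assert_allclose(out, [0, 0, 0, 0, 0, 0.5, 1, 0.5, 0])

    def test_leading_baseline_is_zeroed_and_range_is_one(self):
        lsf = esf_to_lsf(upsample_esf(erf_esf(0.5), 5))
        assert lsf.values[:5].mean() == pytest.approx(0.0, abs=1e-12)
        assert lsf.values.max() - lsf.values.min() == pytest.approx(1.0)

    def test_negative_going_edge_is_flipped(self):
        esf = erf_esf(0.5)
        flipped = ESFCurve(positions_mm=esf.positions_mm,
                           values_hu=esf.values_hu[::-1].copy())
        lsf = esf_to_lsf(upsample_esf(flipped, 5))
        assert lsf.values.max() > 0.9  # dominant peak is positive after flip
        assert lsf.values.max() - lsf.values.min() == pytest.approx(1.0)

    def test_linear_esf_has_no_edge(self):
        esf = ESFCurve(positions_mm=np.arange(41) * 0.5,
                       values_hu=5.0 * np.arange(41.0))
        with pytest.raises(DegenerateLSFError, match="degenerate"):
            esf_to_lsf(esf)

    def test_peak_sits_at_the_edge_position(self):
        sigma = 0.5
        esf = upsample_esf(erf_esf(sigma), 5)
        lsf = esf_to_lsf(esf)
        peak_pos = lsf.positions_mm[np.argmax(lsf.values)]
        assert abs(peak_pos - 20 * 0.5) <= lsf.spacing_mm


class TestLSFToMTF:
    def test_unit_impulse_has_flat_modulation(self):
        values = np.zeros(201)
        values[100] = 1.0
        lsf = LSFCurve(positions_mm=np.arange(201) * 0.1, values=values)
        mtf = lsf_to_mtf(lsf, pixel_spacing_mm=0.5, factor=5)
        np.testing.assert_allclose(mtf.modulation, 1.0, atol=1e-12)

    def test_bin_spacing_and_truncation(self):
        lsf = esf_to_lsf(upsample_esf(erf_esf(0.5), 5))
        mtf = lsf_to_mtf(lsf, 0.5, 5)
        df = mtf.frequencies_lp_per_cm[1] - mtf.frequencies_lp_per_cm[0]
        assert df == pytest.approx(10.0 / (201 * 0.1), rel=1e-9)  # 0.4975 lp/cm
        assert mtf.frequencies_lp_per_cm[-1] <= mtf.nyquist_lp_per_cm
        assert mtf.nyquist_lp_per_cm == pytest.approx(10.0)

    def test_gaussian_lsf_matches_closed_form(self):
        """A directly sampled Gaussian LSF on a wide window transforms to
        exp(-2 pi^2 sigma^2 f^2) within 1% up to 5 lp/cm."""
        sigma = 0.5
        spacing, factor = 0.5, 5
        n = 1001
        pos = (np.arange(n) - n // 2) * (spacing / factor)
        lsf = LSFCurve(positions_mm=pos + n // 2 * 0.1,
                       values=np.exp(-pos**2 / (2 * sigma**2)))
        mtf = lsf_to_mtf(lsf, spacing, factor)
        f_cpm = mtf.frequencies_lp_per_cm / 10.0
        expected = np.exp(-2 * np.pi**2 * sigma**2 * f_cpm**2)
        band = mtf.frequencies_lp_per_cm <= 5.0
        np.testing.assert_allclose(mtf.modulation[band], expected[band], rtol=0.01)

    def test_zero_dc_is_an_error(self):
        values = np.zeros(201)
        lsf = LSFCurve(positions_mm=np.arange(201) * 0.1, values=values)
        with pytest.raises(DegenerateLSFError):
            lsf_to_mtf(lsf, 0.5, 5)


class TestMTFModelFit:
    def test_model_is_one_at_zero_frequency(self):
        for params in (MTFFitParams(0.3, 1.2, 0.7, 2.0),
                       MTFFitParams(1.0, 0.1, 2.0, 0.5)):
            assert params(0.0) == pytest.approx(1.0)

    def test_self_consistency_recovery(self):
        truth = MTFFitParams(a=0.3, b=1.2, c=0.7, d=2.0)
        freqs = np.arange(0.0, 10.05, 0.05)
        curve = MTFCurve(frequencies_lp_per_cm=freqs, modulation=truth(freqs),
                         nyquist_lp_per_cm=10.0)
        fit = fit_mtf_model(curve)
        for name in "abcd":
            assert getattr(fit, name) == pytest.approx(getattr(truth, name),
                                                       rel=1e-3)

    def test_noise_increases_fit_residual(self):
        sigma = 0.5
        freqs = np.arange(0.0, 10.05, 0.05)
        clean = np.exp(-2 * np.pi**2 * sigma**2 * (freqs / 10.0) ** 2)
        rng = np.random.default_rng(1)
        noisy = np.clip(clean + rng.normal(0, 0.02, clean.size), 0, None)
        noisy[0] = 1.0

        def residual(mod):
            curve = MTFCurve(frequencies_lp_per_cm=freqs, modulation=mod,
                             nyquist_lp_per_cm=10.0)
            fit = fit_mtf_model(curve)
            return np.sum((fit(freqs) - mod) ** 2)

        assert residual(clean) <= residual(noisy)

    def test_too_few_samples(self):
        curve = MTFCurve(frequencies_lp_per_cm=np.arange(5.0),
                         modulation=np.exp(-0.1 * np.arange(5.0)),
                         nyquist_lp_per_cm=10.0)
        with pytest.raises(Exception, match="at least 8"):
            fit_mtf_model(curve)


class TestResolutionMetrics:
    def analytic_curve(self, sigma, fmax=12.0, step=0.001):
        freqs = np.arange(0.0, fmax, step)
        mod = np.exp(-2 * np.pi**2 * sigma**2 * (freqs / 10.0) ** 2)
        return MTFCurve(frequencies_lp_per_cm=freqs, modulation=mod,
                        nyquist_lp_per_cm=fmax)

    def test_closed_form_crossings(self):
        res = resolution_metrics(self.analytic_curve(0.5))
        assert res.f50_lp_per_cm == pytest.approx(3.748, abs=2e-3)
        assert res.f10_lp_per_cm == pytest.approx(6.831, abs=2e-3)
        assert res.f50_lp_per_cm == pytest.approx(gaussian_f50(0.5), rel=1e-4)
        assert res.f10_lp_per_cm == pytest.approx(gaussian_f10(0.5), rel=1e-4)

    def test_exact_grid_hit_returned_verbatim(self):
        freqs = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        mod = np.array([1.0, 0.8, 0.5, 0.3, 0.05])
        curve = MTFCurve(frequencies_lp_per_cm=freqs, modulation=mod,
                         nyquist_lp_per_cm=10.0)
        res = resolution_metrics(curve)
        assert res.f50_lp_per_cm == 2.0

    def test_no_crossing_is_beyond_nyquist_error(self):
        freqs = np.arange(0.0, 5.0, 0.5)
        mod = np.exp(-0.05 * freqs)  # stays above 0.5
        curve = MTFCurve(frequencies_lp_per_cm=freqs, modulation=mod,
                         nyquist_lp_per_cm=5.0)
        with pytest.raises(ResolutionBeyondNyquistError, match="beyond Nyquist"):
            resolution_metrics(curve)

    def test_ordering_invariant(self):
        res = resolution_metrics(self.analytic_curve(0.3))
        assert res.f50_lp_per_cm < res.f10_lp_per_cm


class TestMeasureSequence:
    def test_noiseless_sequence_matches_ground_truth(self, default_spec):
        series = generate_sequence(default_spec, 20)
        result = measure_sequence(series)
        assert result.pooled.f50_lp_per_cm == pytest.approx(gaussian_f50(0.5),
                                                            rel=0.03)
        assert result.pooled.f10_lp_per_cm == pytest.approx(gaussian_f10(0.5),
                                                            rel=0.03)
        assert result.pooled.mode == "pooled"
        assert result.pooled_mtf.modulation[0] == pytest.approx(1.0)

    def test_single_slice_pooled_equals_per_slice(self, small_spec):
        series = generate_sequence(small_spec, 1)
        config = MeasurementConfig(fit_model=False)
        result = measure_sequence(series, config)
        assert result.pooled.f50_lp_per_cm == \
            pytest.approx(result.per_slice[0].f50_lp_per_cm, rel=1e-9)
        assert result.pooled.f10_lp_per_cm == \
            pytest.approx(result.per_slice[0].f10_lp_per_cm, rel=1e-9)

    def test_noisy_measurement_is_deterministic(self, small_spec):
        spec = dataclasses.replace(small_spec, noise_sd_hu=15.0, seed=42)
        series = generate_sequence(spec, 6)
        r1 = measure_sequence(series)
        r2 = measure_sequence(generate_sequence(spec, 6))
        assert r1.pooled == r2.pooled
        assert r1.per_slice == r2.per_slice

    def test_every_result_orders_f50_before_f10(self, small_spec):
        spec = dataclasses.replace(small_spec, noise_sd_hu=15.0, seed=11)
        result = measure_sequence(generate_sequence(spec, 6))
        for res in [result.pooled, *result.per_slice.values()]:
            assert res.f50_lp_per_cm < res.f10_lp_per_cm
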
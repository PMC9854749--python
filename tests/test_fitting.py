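import numpy as np
import pytest

from ivimtex.fitting import (
    FitConfig,
    fit_adc_voxel,
    fit_idtv_volume,
    fit_ivimdki_voxel,
    fit_standard_volume,
    goodness_of_fit,
)
from ivimtex.models import DiffusionParams, default_scheme, ivim_dki_signal
from ivimtex.phantom import CLASS_PARAMS
from ivimtex.tv import tv_norm

from oracles import adc_loglinear_oracle

ADC_B = np.array([0.0, 500.0, 800.0, 1000.0])


def sample_valid_params(rng, n):
    """Physiological IVIM-DKI draws inside the fit box, restricted to the
    kurtosis-model validity region b_max <= 3/(D k) (outside it the
    printed signal equation blows up at high b)."""
    out = []
    for _ in range(n):
        D = rng.uniform(0.4e-3, 3e-3)
        k = rng.uniform(0.3, min(2.0, 3.0 / (2500 * D)))
        out.append((D, rng.uniform(5e-3, 100e-3), rng.uniform(0.05, 0.45), k))
    return out


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        y = np.linspace(1, 0.2, 14)
        assert goodness_of_fit(y, y, 4) == (1.0, 1.0)

    def test_adjustment_formula(self):
        # R2=0.95, n=14, p=4: adj = 1 - 0.05*13/9
        y = np.arange(14.0)
        ss_tot = np.sum((y - y.mean()) ** 2)
        resid = np.sqrt(0.05 * ss_tot / 14)
        yhat = y + resid * np.where(np.arange(14) % 2 == 0, 1, -1)
        r2, adj = goodness_of_fit(y, yhat, 4)
        assert r2 == pytest.approx(0.95)
        assert adj == pytest.approx(1 - 0.05 * 13 / 9)

    def test_mean_prediction_gives_zero(self):
        y = np.linspace(1, 0.2, 14)
        r2, _ = goodness_of_fit(y, np.full(14, y.mean()), 4)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_observed_flagged(self):
        r2, adj = goodness_of_fit(np.ones(14), np.ones(14), 4)
        assert np.isnan(r2) and np.isnan(adj)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit(np.ones(5), np.ones(5), 4)


class TestAdcFit:
    def test_noiseless_recovery(self):
        s = np.exp(-ADC_B * 1.7e-3)
        adc, r2 = fit_adc_voxel(s, ADC_B)
        assert adc == pytest.approx(1.7e-3, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_constant_signal_gives_zero_adc(self):
        adc, _ = fit_adc_voxel(np.ones(4), ADC_B)
        assert adc == pytest.approx(0.0, abs=1e-8)

    def test_matches_loglinear_oracle_on_noiseless_signals(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            truth = rng.uniform(0.5e-3, 3e-3)
            s = np.exp(-ADC_B * truth)
            adc, _ = fit_adc_voxel(s, ADC_B)
            assert adc == pytest.approx(adc_loglinear_oracle(s, ADC_B),
                                        abs=1e-6 * truth)

    def test_bad_signal_flagged_missing(self):
        adc, r2 = fit_adc_voxel([1.0, np.nan, 0.4, 0.3], ADC_B)
        assert np.isnan(adc) and np.isnan(r2)


class TestIvimDkiVoxelFit:
    def test_start_point_is_recovered_when_optimal(self, scheme):
        truth = DiffusionParams(1.3e-3, 13e-3, 0.3, 0.7)
        s = ivim_dki_signal(truth, scheme.b)
        est, rss, r2, ok = fit_ivimdki_voxel(s, scheme)
        np.testing.assert_allclose(est.as_array(), truth.as_array(), rtol=1e-6)
        assert rss < 1e-20 and r2 == pytest.approx(1.0) and ok

    @pytest.mark.parametrize("cls", sorted(CLASS_PARAMS))
    def test_class_mean_parameters_recovered(self, scheme, cls):
        p = CLASS_PARAMS[cls]
        truth = DiffusionParams(p["D"][0], p["Dstar"][0], p["f"][0], p["k"][0])
        s = ivim_dki_signal(truth, scheme.b)
        est, _, _, _ = fit_ivimdki_voxel(s, scheme)
        assert est.D == pytest.approx(truth.D, rel=0.01)
        assert est.f == pytest.approx(truth.f, rel=0.01)
        assert est.k == pytest.approx(truth.k, rel=0.01)
        assert est.Dstar == pytest.approx(truth.Dstar, rel=0.10)

    def test_vanishing_perfusion_fraction(self, scheme):
        truth = DiffusionParams(1.5e-3, 50e-3, 0.0, 0.8)
        s = ivim_dki_signal(truth, scheme.b)
        est, _, _, _ = fit_ivimdki_voxel(s, scheme)
        assert est.f <= 0.02
        assert est.D == pytest.approx(truth.D, rel=0.01)

    def test_noiseless_recovery_sweep(self, scheme):
        # median relative error: D, f, k < 1%; D* < 10%
        rng = np.random.default_rng(42)
        errs = []
        for D, Ds, f, k in sample_valid_params(rng, 100):
            s = ivim_dki_signal((D, Ds, f, k), scheme.b, validate=False)
            e, _, _, _ = fit_ivimdki_voxel(s, scheme)
            errs.append([abs(e.D - D) / D, abs(e.Dstar - Ds) / Ds,
                         abs(e.f - f) / f, abs(e.k - k) / k])
        med = np.median(errs, axis=0)
        assert med[0] < 0.01 and med[2] < 0.01 and med[3] < 0.01
        assert med[1] < 0.10


class TestVolumeFits:
    def test_noiseless_phantom_recovered_voxelwise(self, noiseless_phantom):
        case = noiseless_phantom
        res = fit_standard_volume(case.signal4d, case.scheme, case.organ_mask)
        m = case.organ_mask
        np.testing.assert_allclose(res.maps.d[m], case.truth.d[m], rtol=0.01)
        np.testing.assert_allclose(res.maps.f[m], case.truth.f[m], atol=0.01)
        np.testing.assert_allclose(res.maps.k[m], case.truth.k[m], rtol=0.02)
        assert res.mean_adj_r2 == pytest.approx(1.0, abs=1e-6)

    def test_empty_mask_returns_empty_maps(self, noiseless_phantom, caplog):
        case = noiseless_phantom
        res = fit_standard_volume(case.signal4d, case.scheme,
                                  np.zeros_like(case.organ_mask))
        assert np.all(np.isnan(res.maps.d))
        assert np.isnan(res.mean_adj_r2)

    def test_single_voxel_mask_reduces_to_voxel_fit(self, noiseless_phantom,
                                                    scheme):
        case = noiseless_phantom
        ix, iy, iz = (int(v[0]) for v in np.nonzero(case.organ_mask))
        mask1 = np.zeros_like(case.organ_mask)
        mask1[ix, iy, iz] = True
        vol_res = fit_standard_volume(case.signal4d, case.scheme, mask1)
        p, _, _, _ = fit_ivimdki_voxel(case.signal4d[ix, iy, iz], case.scheme)
        assert vol_res.maps.d[ix, iy, iz] == pytest.approx(p.D)
        assert vol_res.maps.f[ix, iy, iz] == pytest.approx(p.f)
        # IDTV on a single voxel: TV term vanishes, equals the standard fit
        idtv_res = fit_idtv_volume(case.signal4d, case.scheme, mask1)
        assert idtv_res.maps.d[ix, iy, iz] == pytest.approx(p.D)

    def test_shape_mismatch_errors_name_axes(self, noiseless_phantom):
        case = noiseless_phantom
        with pytest.raises(ValueError, match="b-axis|scheme"):
            fit_standard_volume(case.signal4d[..., :5], case.scheme,
                                case.organ_mask)
        with pytest.raises(ValueError, match="mask"):
            fit_standard_volume(case.signal4d, case.scheme,
                                case.organ_mask[1:, :, :])

    def test_voxel_order_invariance(self, noiseless_phantom):
        # fitting a sub-mask gives bit-identical values to the full run
        case = noiseless_phantom
        full = fit_standard_volume(case.signal4d, case.scheme, case.organ_mask)
        sub_mask = case.organ_mask.copy()
        coords = np.nonzero(sub_mask)
        half = len(coords[0]) // 2
        sub_mask[coords[0][half:], coords[1][half:], coords[2][half:]] = False
        sub = fit_standard_volume(case.signal4d, case.scheme, sub_mask)
        np.testing.assert_array_equal(sub.maps.d[sub_mask],
                                      full.maps.d[sub_mask])


@pytest.fixture(scope="module")
def fits(small_noisy_phantom):
    case = small_noisy_phantom
    std = fit_standard_volume(case.signal4d, case.scheme, case.organ_mask)
    idtv = fit_idtv_volume(case.signal4d, case.scheme, case.organ_mask,
                           FitConfig(model="idtv", max_outer_iters=6))
    return case, std, idtv


class TestIdtv:
    def test_idtv_reduces_lesion_cv_of_d_f_k(self, fits):
        case, std, idtv = fits
        les = case.lesion_mask
        for name in ("d", "f", "k"):
            vs = getattr(std.maps, name)[les]
            vi = getattr(idtv.maps, name)[les]
            cv_s = np.std(vs, ddof=1) / vs.mean()
            cv_i = np.std(vi, ddof=1) / vi.mean()
            assert cv_i < cv_s, name

    def test_idtv_reduces_rmse_vs_truth(self, fits):
        case, std, idtv = fits
        les = case.lesion_mask
        for name in ("d", "f", "k"):
            t = getattr(case.truth, name)[les]
            e_s = np.sqrt(np.mean((getattr(std.maps, name)[les] - t) ** 2))
            e_i = np.sqrt(np.mean((getattr(idtv.maps, name)[les] - t) ** 2))
            assert e_i < e_s, name

    def test_idtv_maps_are_smoother(self, fits):
        case, std, idtv = fits
        m = case.organ_mask
        for name in ("d", "f", "k"):
            tv_s = tv_norm(np.where(m, getattr(std.maps, name), 0), m)
            tv_i = tv_norm(np.where(m, getattr(idtv.maps, name), 0), m)
            assert tv_i <= tv_s, name

    def test_idtv_preserves_goodness_of_fit(self, fits):
        _, std, idtv = fits
        assert idtv.mean_adj_r2 >= std.mean_adj_r2 - 0.01

    def test_idtv_unbiased_on_clean_data(self, noiseless_phantom):
        case = noiseless_phantom
        idtv = fit_idtv_volume(case.signal4d, case.scheme, case.organ_mask,
                               FitConfig(model="idtv", max_outer_iters=3))
        m = case.organ_mask
        np.testing.assert_allclose(idtv.maps.d[m], case.truth.d[m], rtol=0.02)
        np.testing.assert_allclose(idtv.maps.f[m], case.truth.f[m], atol=0.02)
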
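"""ADC fitting, region histograms, Gaussian fits and cohort statistics."""

import numpy as np
import pandas as pd
import pytest

from fetomri.adc import (
    GaussianFit,
    UnitFit,
    compare_models,
    fit_adc,
    fit_gaussian,
    longitudinal_summary,
    per_animal_breakdown,
    roi_histogram,
    variance_components,
    voxel_moments,
)
from fetomri.experiments import _eroded_roi, unit_region_fits
from fetomri.phantom import CohortSpec, build_phantom, sample_cohort
from fetomri.spen import DiffusionModule, DwiSeries, simulate_dwi_series


def make_series(s0, sb, b0=0.0, b=750.0, n=3):
    """Hand-built mono-exponential series: one b≈0 image plus n directions."""
    dms = tuple(
        DiffusionModule(3.2, 10.0, 33.0, tuple(np.eye(3)[i])) for i in range(n)
    )
    shape = np.shape(s0)
    images = np.stack([np.asarray(s0)] + [np.asarray(sb)] * n)
    bmaps = np.stack([np.full(shape, b0)] + [np.full(shape, b)] * n)
    return DwiSeries(
        images=images,
        bmaps=bmaps,
        modules=(None,) + dms,
        nominal_b=(b0,) + (b,) * n,
        noise_sigma=0.0,
    )


class TestFitAdc:
    def test_analytic_example(self):
        series = make_series(np.ones((8, 8)), np.full((8, 8), np.exp(-0.75)))
        amap = fit_adc(series)
        assert np.allclose(amap.adc, 1.0e-3, rtol=1e-12)
        assert np.allclose(amap.directional_adc, 1.0e-3, rtol=1e-12)
        assert amap.valid_mask.all()

    def test_equal_signals_zero_adc(self):
        series = make_series(np.ones((4, 4)), np.ones((4, 4)))
        assert np.allclose(fit_adc(series).adc, 0.0)

    def test_noiseless_exactness(self, rng):
        truth = rng.uniform(0.3e-3, 3e-3, size=(16, 16))
        b0map = rng.uniform(20, 60, size=(16, 16))
        bmap = rng.uniform(700, 780, size=(16, 16))
        s0 = np.exp(-b0map * truth)
        sb = np.exp(-bmap * truth)
        dms = tuple(
            DiffusionModule(3.2, 10.0, 33.0, tuple(np.eye(3)[i])) for i in range(3)
        )
        series = DwiSeries(
            images=np.stack([s0, sb, sb, sb]),
            bmaps=np.stack([b0map, bmap, bmap, bmap]),
            modules=(None,) + dms,
            nominal_b=(0, 750, 750, 750),
            noise_sigma=0.0,
        )
        assert np.allclose(fit_adc(series).adc, truth, rtol=1e-10)

    def test_simulation_recovery_per_compartment(self, spen_params_64):
        ph = build_phantom("wildtype", 14.5, (64, 64), seed=7)
        series = simulate_dwi_series(ph, spen_params_64, snr=50, seed=7)
        amap = fit_adc(series)
        for roi in ("amniotic_fluid", "decidua", "labyrinth", "fetal_brain"):
            mask = _eroded_roi(ph, roi)
            fitted = np.median(amap.adc[mask])
            truth = np.median(ph.truth_maps["adc"][mask])
            assert abs(fitted - truth) / truth < 0.05

    def test_missing_b0_rejected(self):
        series = make_series(np.ones((4, 4)), np.ones((4, 4)))
        series = DwiSeries(
            images=series.images[1:],
            bmaps=series.bmaps[1:],
            modules=series.modules[1:],
            nominal_b=series.nominal_b[1:],
        )
        with pytest.raises(ValueError, match="b≈0"):
            fit_adc(series)


class TestHistogram:
    def test_counts_sum_to_masked_voxels(self, rng):
        values = rng.normal(1.2e-3, 2e-4, size=(32, 32))
        mask = rng.random((32, 32)) > 0.4
        hist = roi_histogram(values, mask)
        assert hist.counts.sum() == mask.sum() == hist.n_voxels

    def test_single_valued_roi_single_occupied_bin(self):
        values = np.full((10, 10), 1.5e-3)
        hist = roi_histogram(values, np.ones((10, 10), bool))
        assert np.count_nonzero(hist.counts) == 1

    def test_additivity_of_disjoint_rois(self, rng):
        values = rng.normal(1e-3, 2e-4, size=(40, 40))
        m1 = np.zeros((40, 40), bool)
        m2 = np.zeros((40, 40), bool)
        m1[:20] = True
        m2[20:] = True
        edges = np.histogram_bin_edges(values, bins=12)
        h1 = roi_histogram(values, m1, bin_edges=edges)
        h2 = roi_histogram(values, m2, bin_edges=edges)
        hu = roi_histogram(values, m1 | m2, bin_edges=edges)
        assert np.array_equal(h1.counts + h2.counts, hu.counts)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="no valid voxels"):
            roi_histogram(rng.random((8, 8)), np.zeros((8, 8), bool))

    def test_voxel_order_invariance(self, rng):
        values = rng.normal(1e-3, 2e-4, size=400)
        edges = np.histogram_bin_edges(values, bins=10)
        h1 = roi_histogram(values.reshape(20, 20), np.ones((20, 20), bool),
                           bin_edges=edges)
        perm = rng.permutation(400).reshape(20, 20)
        h2 = roi_histogram(values[perm], np.ones((20, 20), bool), bin_edges=edges)
        assert np.array_equal(h1.counts, h2.counts)


class TestGaussianFit:
    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(1.2e-3, 2e-4, size=2000)
        hist = roi_histogram(draws.reshape(40, 50), np.ones((40, 50), bool))
        fit = fit_gaussian(hist)
        assert abs(fit.mu - 1.2e-3) / 1.2e-3 < 0.02
        assert abs(fit.sigma - 2e-4) / 2e-4 < 0.05
        assert fit.goodness > 0.9 and not fit.degenerate

    def test_symmetric_histogram_centered_mu(self):
        from fetomri.adc import RoiHistogram

        edges = np.linspace(0.0, 1.0, 6)
        counts = np.array([1, 5, 9, 5, 1])
        hist = RoiHistogram(bin_edges=edges, counts=counts, n_voxels=21)
        fit = fit_gaussian(hist)
        assert fit.mu == pytest.approx(0.5, abs=1e-9)

    def test_amplitude_scaling_invariance(self):
        from fetomri.adc import RoiHistogram

        rng = np.random.default_rng(8)
        draws = rng.normal(0.0, 1.0, size=3000)
        edges = np.linspace(-4, 4, 20)
        counts, _ = np.histogram(draws, bins=edges)
        h1 = RoiHistogram(bin_edges=edges, counts=counts, n_voxels=int(counts.sum()))
        c7 = counts * 7
        h7 = RoiHistogram(bin_edges=edges, counts=c7, n_voxels=int(c7.sum()))
        f1, f7 = fit_gaussian(h1), fit_gaussian(h7)
        assert abs(f1.mu - f7.mu) < 1e-12
        assert abs(f1.sigma - f7.sigma) < 1e-12

    def test_too_few_occupied_bins_rejected(self):
        from fetomri.adc import RoiHistogram

        edges = np.linspace(0, 1, 9)
        counts = np.array([0, 0, 10, 12, 0, 0, 0, 0])
        hist = RoiHistogram(bin_edges=edges, counts=counts, n_voxels=22)
        with pytest.raises(ValueError, match="occupied"):
            fit_gaussian(hist)

    def test_sigma_collapse_flagged(self):
        from fetomri.adc import RoiHistogram

        edges = np.linspace(0, 1, 9)
        counts = np.array([1, 1, 1, 5000, 1, 1, 1, 1])
        hist = RoiHistogram(bin_edges=edges, counts=counts, n_voxels=5007)
        fit = fit_gaussian(hist)
        assert fit.degenerate


def _fit(mu, sigma=1e-4, **meta):
    return UnitFit(
        fit=GaussianFit(mu=mu, sigma=sigma, amplitude=1.0, goodness=1.0),
        model_class=meta.get("model", "wildtype"),
        dam_id=meta.get("dam", 0),
        unit_id=meta.get("unit", 0),
        gestational_day=meta.get("day", 14.5),
        roi_label=meta.get("roi", "placenta"),
    )


class TestCohortStatistics:
    def test_single_unit_zero_spread(self):
        table = longitudinal_summary([_fit(1e-3)])
        assert table.loc[0, "mu_spread"] == 0.0 and table.loc[0, "n_units"] == 1

    def test_two_unit_mean(self):
        table = longitudinal_summary(
            [_fit(1e-3, unit=0), _fit(2e-3, unit=1)]
        )
        assert table.loc[0, "mu_mean"] == pytest.approx(1.5e-3)

    def test_brain_mu_decreases_with_day_truth_level(self):
        spec = CohortSpec("wildtype", 2, (2, 2), (14.5, 16.5, 18.5), seed=5)
        fits = []
        for ph in sample_cohort(spec, grid_shape=(64, 64)):
            hist = roi_histogram(
                ph.truth_maps["adc"], ph.roi("fetal_brain"), roi_label="fetal_brain"
            )
            fits.append(
                UnitFit(
                    fit=fit_gaussian(hist),
                    model_class="wildtype",
                    dam_id=ph.dam_id,
                    unit_id=ph.unit_id,
                    gestational_day=ph.gestational_day,
                    roi_label="fetal_brain",
                )
            )
        table = longitudinal_summary(fits).sort_values("gestational_day")
        assert np.all(np.diff(table["mu_mean"]) < 0)

    def test_compare_models_identical_tables(self):
        table = longitudinal_summary([_fit(1e-3, unit=0), _fit(1.1e-3, unit=1)])
        res = compare_models(table, table, "mu", 14.5)
        assert res["difference"] == 0.0
        assert res["p_value"] == pytest.approx(1.0)

    def test_compare_models_needs_two_units(self):
        t1 = longitudinal_summary([_fit(1e-3)])
        t2 = longitudinal_summary([_fit(1e-3, unit=0), _fit(1.2e-3, unit=1)])
        with pytest.raises(ValueError, match="2 units"):
            compare_models(t1, t2, "mu", 14.5)

    def test_per_animal_single_dam_matches_summary(self):
        fits = [_fit(1e-3, unit=0), _fit(1.4e-3, unit=1)]
        summ = longitudinal_summary(fits)
        brk = per_animal_breakdown(fits)
        assert len(brk) == 1
        assert brk.loc[0, "mu_mean"] == summ.loc[0, "mu_mean"]
        assert brk.loc[0, "sigma_mean"] == summ.loc[0, "sigma_mean"]

    def test_per_animal_order_invariance(self):
        fits = [
            _fit(1e-3, dam=0, unit=0),
            _fit(1.2e-3, dam=0, unit=1),
            _fit(0.9e-3, dam=1, unit=0),
        ]
        a = per_animal_breakdown(fits)
        b = per_animal_breakdown(fits[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_variance_components_detect_dam_bias(self):
        rng = np.random.default_rng(11)
        biased, unbiased = [], []
        for dam in range(4):
            bias = dam * 3e-4
            for unit in range(6):
                noise = rng.normal(0, 2e-5)
                biased.append(_fit(1e-3 + bias + noise, dam=dam, unit=unit))
                unbiased.append(_fit(1e-3 + noise, dam=dam, unit=unit))
        vb = variance_components(biased)
        vu = variance_components(unbiased)
        assert vb["between_dam"] > vb["within_dam"]
        assert vu["between_dam"] < 10 * vu["within_dam"]

    def test_unit_region_fits_cover_all_rois(self, spen_params_64):
        ph = build_phantom("wildtype", 14.5, (64, 64), seed=2)
        series = simulate_dwi_series(ph, spen_params_64, snr=40, seed=2)
        amap = fit_adc(series)
        fits = unit_region_fits(ph, amap, "wildtype")
        assert {f.roi_label for f in fits} >= {"placenta", "fetal_brain",
                                               "amniotic_fluid"}
        for f in fits:
            assert f.fit.sigma > 0
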
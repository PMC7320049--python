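"""Synthetic-dataset generators: alterations, labels, sampling ranges, determinism."""

import numpy as np
import pytest
from scipy import stats

from nmrcal import (
    SpectralGrid,
    Spectrum,
    XiConfig,
    XiiConfig,
    broaden_spectrum,
    eval_component,
    extract_noise_pool,
    integrate_area,
    make_dataset_xi,
    make_dataset_xii,
    shift_spectrum,
)

LB_SET = (0.2, 0.5, 0.8, 1.0, 1.5)


class TestBroadenSpectrum:
    def test_zero_broadening_is_identity(self, toy_lib):
        s = toy_lib.pure_spectra[0]
        out = broaden_spectrum(s, 0.0)
        assert np.array_equal(out.intensity, s.intensity)

    @pytest.mark.parametrize("lb", LB_SET)
    def test_integral_preserved(self, toy_lib, lb):
        s = toy_lib.pure_spectra[1]  # interior peaks
        a0 = integrate_area(s)
        a1 = integrate_area(broaden_spectrum(s, lb))
        assert a1 == pytest.approx(a0, rel=0.005)

    def test_peak_maximum_strictly_decreases_with_broadening(self, toy_lib):
        s = toy_lib.pure_spectra[0]
        maxima = [broaden_spectrum(s, lb).intensity.max() for lb in LB_SET]
        assert all(b < a for a, b in zip(maxima, maxima[1:]))

    def test_negative_broadening_rejected(self, toy_lib):
        with pytest.raises(ValueError):
            broaden_spectrum(toy_lib.pure_spectra[0], -0.1)


class TestShiftSpectrum:
    def test_zero_shift_is_identity(self, toy_lib):
        s = toy_lib.pure_spectra[0]
        assert np.array_equal(shift_spectrum(s, 0.0).intensity, s.intensity)

    def test_exact_grid_step_shift_is_index_shift(self, toy_lib):
        s = toy_lib.pure_spectra[0]
        d = s.grid.dppm
        out = shift_spectrum(s, d)
        assert np.allclose(out.intensity[1:], s.intensity[:-1], atol=1e-9)
        assert out.intensity[0] == 0.0

    def test_area_preserved_for_interior_peaks(self, toy_lib):
        s = toy_lib.pure_spectra[2]
        a0 = integrate_area(s)
        assert integrate_area(shift_spectrum(s, 0.015)) == pytest.approx(a0, rel=0.005)
        assert integrate_area(shift_spectrum(s, -0.015)) == pytest.approx(a0, rel=0.005)


class TestNoisePool:
    def test_pool_std_matches_generating_noise(self):
        grid = SpectralGrid(5.6, 9.0, 20000)
        rng = np.random.default_rng(5)
        blank = Spectrum(grid, rng.normal(0.0, 0.05, 20000))
        pool = extract_noise_pool(blank, [(5.6, 9.0)])
        assert pool.samples.size >= 5000
        assert pool.samples.std() == pytest.approx(0.05, rel=0.05)

    def test_all_zero_region_gives_zero_pool(self):
        grid = SpectralGrid(5.6, 9.0, 500)
        pool = extract_noise_pool(Spectrum(grid, np.zeros(500)), [(6.0, 7.0)])
        assert np.all(pool.samples == 0.0)

    def test_region_outside_grid_raises(self, toy_lib):
        blank = Spectrum(toy_lib.grid, np.zeros(toy_lib.grid.n_points))
        with pytest.raises(ValueError):
            extract_noise_pool(blank, [(10.0, 11.0)])

    def test_empty_region_list_raises(self, toy_lib):
        with pytest.raises(ValueError):
            extract_noise_pool(toy_lib.pure_spectra[0], [])


class TestMakeDatasetXi:
    @pytest.fixture(scope="class")
    @staticmethod
    def ds(toy_lib):
        return make_dataset_xi(toy_lib.pure_spectra, XiConfig(n_spectra=150, seed=21))

    def test_label_conservation(self, ds):
        """Sum of labels equals the mixture integral (up to embedded noise)."""
        totals = np.trapezoid(ds.spectra, ds.grid.ppm, axis=1)
        assert np.allclose(ds.labels.sum(axis=1), totals, rtol=0.01)

    def test_sampled_parameters_inside_ranges(self, ds):
        log = ds.params_log
        for name in ds.component_names:
            assert set(np.unique(log[f"{name}__lb_hz"])) <= set(LB_SET)
            assert np.all(np.abs(log[f"{name}__shift_ppm"]) <= 0.015)
            areas = log[f"{name}__area"]
            assert np.all((areas >= 0) & (areas <= 180))

    def test_determinism_bit_identical(self, toy_lib):
        cfg = XiConfig(n_spectra=20, seed=77)
        a = make_dataset_xi(toy_lib.pure_spectra, cfg)
        b = make_dataset_xi(toy_lib.pure_spectra, cfg)
        assert np.array_equal(a.spectra, b.spectra)
        assert np.array_equal(a.labels, b.labels)
        assert a.params_log.equals(b.params_log)

    def test_labels_are_exact_target_areas(self, ds):
        for j, name in enumerate(ds.component_names):
            assert np.allclose(ds.labels[:, j], ds.params_log[f"{name}__area"])


class TestMakeDatasetXii:
    @pytest.fixture(scope="class")
    @staticmethod
    def ds_clean(toy_lib):
        cfg = XiiConfig(n_spectra=200, seed=31, add_noise=False)
        return make_dataset_xii(toy_lib.mixture, None, cfg, grid=toy_lib.grid)

    def test_label_conservation_noise_free(self, ds_clean):
        totals = np.trapezoid(ds_clean.spectra, ds_clean.grid.ppm, axis=1)
        assert np.allclose(ds_clean.labels.sum(axis=1), totals, rtol=0.005)

    def test_sampled_parameters_inside_ranges(self, ds_clean):
        log = ds_clean.params_log
        for name in ds_clean.component_names:
            assert np.all(np.abs(log[f"{name}__shift_ppm"]) <= 0.015)
            assert np.all(np.abs(log[f"{name}__broadening"] - 1.0) <= 0.15)
            assert np.all((log[f"{name}__area"] >= 0) & (log[f"{name}__area"] <= 180))
            gs_cols = [c for c in log.columns if c.startswith(f"{name}__group_shift_")]
            jit_cols = [c for c in log.columns if c.startswith(f"{name}__jitter_")]
            assert np.all(np.abs(log[gs_cols].to_numpy()) <= 0.01)
            assert np.all(np.abs(log[jit_cols].to_numpy()) <= 0.005)

    def test_zero_target_area_gives_zero_weight_and_absent_component(self, toy_lib):
        cfg = XiiConfig(n_spectra=5, seed=3, add_noise=False, area_range=(0.0, 0.0))
        ds = make_dataset_xii(toy_lib.mixture, None, cfg, grid=toy_lib.grid)
        assert np.all(ds.labels == 0.0)
        assert np.all(ds.spectra == 0.0)

    def test_labels_and_params_invariant_to_noise(self, toy_lib):
        """Noise comes from a separate stream: labels/params identical on/off."""
        on = make_dataset_xii(
            toy_lib.mixture, toy_lib.noise_pool,
            XiiConfig(n_spectra=15, seed=41), grid=toy_lib.grid,
        )
        off = make_dataset_xii(
            toy_lib.mixture, None,
            XiiConfig(n_spectra=15, seed=41, add_noise=False), grid=toy_lib.grid,
        )
        assert np.array_equal(on.labels, off.labels)
        assert not np.array_equal(on.spectra, off.spectra)

    def test_reconstruction_from_params_log(self, toy_lib, ds_clean):
        """Logged parameters regenerate the stored spectrum and labels exactly."""
        i = 7
        log = ds_clean.params_log.iloc[i]
        acc = np.zeros(ds_clean.grid.n_points)
        for j, comp in enumerate(toy_lib.mixture.components):
            gs = [log[f"{comp.name}__group_shift_{g}"] for g in range(comp.n_groups)]
            pj = [log[f"{comp.name}__jitter_{p}"] for p in range(comp.n_peaks)]
            unit = eval_component(
                comp, ds_clean.grid,
                component_shift=log[f"{comp.name}__shift_ppm"],
                group_shift=gs, broadening=log[f"{comp.name}__broadening"],
                peak_jitter=pj,
            )
            w = log[f"{comp.name}__weight"]
            acc += w * unit
            area = np.trapezoid(w * unit, ds_clean.grid.ppm)
            assert area == pytest.approx(ds_clean.labels[i, j], rel=1e-9)
        assert np.allclose(acc, ds_clean.spectra[i], atol=1e-9)

    def test_area_linearity_doubling(self, toy_lib):
        """Doubling a component's target area doubles its contribution."""
        cfg1 = XiiConfig(n_spectra=1, seed=8, add_noise=False, area_range=(50.0, 50.0))
        cfg2 = XiiConfig(n_spectra=1, seed=8, add_noise=False, area_range=(100.0, 100.0))
        d1 = make_dataset_xii(toy_lib.mixture, None, cfg1, grid=toy_lib.grid)
        d2 = make_dataset_xii(toy_lib.mixture, None, cfg2, grid=toy_lib.grid)
        assert np.allclose(d2.spectra, 2.0 * d1.spectra, rtol=1e-9, atol=1e-12)


class TestSamplingUniformity:
    """Each continuous parameter passes a KS test against its uniform range."""

    def test_xii_parameters_uniform(self, toy_lib):
        cfg = XiiConfig(n_spectra=2500, seed=99, add_noise=False)
        ds = make_dataset_xii(toy_lib.mixture, None, cfg, grid=toy_lib.grid)
        log = ds.params_log
        pools = {
            "shift": (np.concatenate(
                [log[f"{n}__shift_ppm"] for n in ds.component_names]), -0.015, 0.015),
            "broadening": (np.concatenate(
                [log[f"{n}__broadening"] for n in ds.component_names]), 0.85, 1.15),
            "area": (np.concatenate(
                [log[f"{n}__area"] for n in ds.component_names]), 0.0, 180.0),
        }
        for name, (draws, lo, hi) in pools.items():
            assert draws.size >= 10_000
            p = stats.kstest(draws, stats.uniform(lo, hi - lo).cdf).pvalue
            assert p > 0.01, f"{name} failed uniformity (p={p:.4f})"

    def test_xi_parameters_uniform_and_broadening_balanced(self, toy_lib):
        cfg = XiConfig(n_spectra=2500, seed=98)
        ds = make_dataset_xi(toy_lib.pure_spectra, cfg)
        log = ds.params_log
        shifts = np.concatenate([log[f"{n}__shift_ppm"] for n in ds.component_names])
        areas = np.concatenate([log[f"{n}__area"] for n in ds.component_names])
        assert stats.kstest(shifts, stats.uniform(-0.015, 0.03).cdf).pvalue > 0.01
        assert stats.kstest(areas, stats.uniform(0, 180).cdf).pvalue > 0.01
        lbs = np.concatenate([log[f"{n}__lb_hz"] for n in ds.component_names])
        counts = np.array([(lbs == v).sum() for v in LB_SET])
        assert stats.chisquare(counts).pvalue > 0.01
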
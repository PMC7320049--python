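"""Line shapes, mixture evaluation, peak grouping and numerical integration."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from nmrcal import (
    MixtureParams,
    PseudoVoigtPeak,
    PureComponentModel,
    SpectralGrid,
    Spectrum,
    assign_groups,
    eval_component,
    eval_mixture,
    eval_peak,
    integrate_area,
)
from .conftest import brute_force_mixture

LN2 = np.log(2.0)


class TestEvalPeak:
    def test_height_normalization_at_center(self):
        # grid step 0.01 ppm contains nu = 7.00 exactly
        grid = SpectralGrid(5.6, 9.0, 341)
        peak = PseudoVoigtPeak(omega=7.0, alpha=2.0, gamma=0.01, beta=1.0)
        y = eval_peak(peak, grid)
        i = np.argmin(np.abs(grid.ppm - 7.0))
        assert y[i] == pytest.approx(2.0, abs=1e-12)

    def test_hwhm_definition(self):
        grid = SpectralGrid(5.6, 9.0, 341)
        peak = PseudoVoigtPeak(omega=7.0, alpha=2.0, gamma=0.01, beta=1.0)
        y = eval_peak(peak, grid)
        i = np.argmin(np.abs(grid.ppm - 7.01))  # one HWHM off-center
        assert y[i] == pytest.approx(1.0, abs=1e-9)

    def test_lorentzian_area_closed_form(self, fine_grid):
        peak = PseudoVoigtPeak(omega=7.0, alpha=2.0, gamma=0.01, beta=1.0)
        area = integrate_area(Spectrum(fine_grid, eval_peak(peak, fine_grid)))
        assert area == pytest.approx(np.pi * 2.0 * 0.01, rel=0.005)

    def test_gaussian_area_closed_form(self, fine_grid):
        peak = PseudoVoigtPeak(omega=7.0, alpha=1.0, gamma=0.02, beta=0.0)
        area = integrate_area(Spectrum(fine_grid, eval_peak(peak, fine_grid)))
        assert area == pytest.approx(0.02 * np.sqrt(np.pi / LN2), rel=0.005)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            PseudoVoigtPeak(omega=7.0, alpha=1.0, gamma=0.0)

    def test_beta_bounds_enforced(self):
        with pytest.raises(ValueError):
            PseudoVoigtPeak(omega=7.0, alpha=1.0, gamma=0.01, beta=1.2)


class TestEvalComponent:
    @pytest.fixture
    def model(self):
        return PureComponentModel.from_peaks(
            "m",
            [
                PseudoVoigtPeak(omega=6.8, alpha=1.0, gamma=0.015, beta=0.5),
                PseudoVoigtPeak(omega=6.85, alpha=2.0, gamma=0.012, beta=0.8),
                PseudoVoigtPeak(omega=7.6, alpha=1.5, gamma=0.02, beta=0.3),
            ],
        )

    def test_identity_parameters_equal_peak_sum(self, model, fine_grid):
        direct = sum(eval_peak(p, fine_grid) for p in model.peaks)
        assert np.allclose(eval_component(model, fine_grid), direct, atol=1e-14)

    def test_component_shift_translates_argmax(self):
        grid = SpectralGrid(5.6, 9.0, 3401)
        model = PureComponentModel.from_peaks(
            "one", [PseudoVoigtPeak(omega=7.0, alpha=1.0, gamma=0.02, beta=1.0)]
        )
        base = np.argmax(eval_component(model, grid))
        shifted = np.argmax(eval_component(model, grid, component_shift=0.1))
        assert abs(grid.ppm[shifted] - grid.ppm[base] - 0.1) <= grid.dppm

    def test_broadening_scales_lorentzian_area_linearly(self, fine_grid):
        model = PureComponentModel.from_peaks(
            "lor", [PseudoVoigtPeak(omega=7.0, alpha=1.0, gamma=0.02, beta=1.0)]
        )
        a0 = integrate_area(Spectrum(fine_grid, eval_component(model, fine_grid)))
        a1 = integrate_area(
            Spectrum(fine_grid, eval_component(model, fine_grid, broadening=1.15))
        )
        assert a1 / a0 == pytest.approx(1.15, rel=0.01)

    def test_length_mismatch_raises(self, model, fine_grid):
        with pytest.raises(ValueError):
            eval_component(model, fine_grid, group_shift=[0.0])  # model has 2 groups
        with pytest.raises(ValueError):
            eval_component(model, fine_grid, peak_jitter=[0.0, 0.0])  # 3 peaks


class TestEvalMixture:
    def test_zero_weights_give_zero_spectrum(self, toy_lib):
        params = MixtureParams.identity(toy_lib.mixture, weights=[0.0] * 4)
        spec = eval_mixture(toy_lib.mixture, toy_lib.grid, params)
        assert np.all(spec.intensity == 0.0)

    def test_linearity_in_weight(self, two_component_mixture):
        grid = SpectralGrid(5.6, 9.0, 500)
        sub = type(two_component_mixture)((two_component_mixture.components[0],))
        one = eval_mixture(sub, grid, MixtureParams.identity(sub, weights=[1.0]))
        two = eval_mixture(sub, grid, MixtureParams.identity(sub, weights=[2.0]))
        assert np.allclose(two.intensity, 2.0 * one.intensity, atol=1e-12)

    def test_matches_per_peak_brute_force(self, toy_lib):
        mixture, grid = toy_lib.mixture, toy_lib.grid
        rng = np.random.default_rng(42)
        params = MixtureParams(
            weights=tuple(rng.uniform(0, 2, 4)),
            component_shift=tuple(rng.uniform(-0.015, 0.015, 4)),
            group_shift=tuple(
                tuple(rng.uniform(-0.01, 0.01, c.n_groups)) for c in mixture.components
            ),
            peak_broadening=tuple(rng.uniform(0.85, 1.15, 4)),
            peak_jitter=tuple(
                tuple(rng.uniform(-0.005, 0.005, c.n_peaks)) for c in mixture.components
            ),
        )
        ours = eval_mixture(mixture, grid, params).intensity
        oracle = brute_force_mixture(mixture, grid, params)
        assert np.allclose(ours, oracle, rtol=1e-13, atol=1e-13)

    def test_inconsistent_params_rejected(self, toy_lib):
        bad = MixtureParams(
            weights=(1.0,), component_shift=(0.0,), group_shift=((0.0,),),
            peak_broadening=(1.0,),
        )
        with pytest.raises(ValueError):
            eval_mixture(toy_lib.mixture, toy_lib.grid, bad)

    @settings(
        deadline=None, max_examples=25,
        suppress_health_check=[HealthCheck.function_scoped_fixture],  # fixture is read-only
    )
    @given(
        w=st.lists(st.floats(0.0, 3.0), min_size=2, max_size=2),
        shift=st.floats(-0.015, 0.015),
    )
    def test_area_linear_in_weights_under_shifts(self, two_component_mixture, w, shift):
        """Total area of a shifted mixture equals the weighted sum of
        component areas (interior peaks, 0.5% tolerance)."""
        grid = SpectralGrid(5.6, 9.0, 1701)
        mix = two_component_mixture
        params = MixtureParams(
            weights=tuple(w),
            component_shift=(shift, -shift),
            group_shift=tuple((0.0,) * c.n_groups for c in mix.components),
            peak_broadening=(1.0, 1.0),
        )
        total = integrate_area(eval_mixture(mix, grid, params))
        parts = sum(
            wk * integrate_area(Spectrum(grid, eval_component(c, grid)))
            for wk, c in zip(w, mix.components)
        )
        assert total == pytest.approx(parts, rel=0.005, abs=1e-9)


class TestAssignGroups:
    @pytest.mark.parametrize(
        "omegas, expected",
        [
            ([7.00, 7.05, 7.30], [0, 0, 1]),  # gaps 0.05 | 0.25 vs 0.12
            ([7.00, 7.11, 7.22], [0, 0, 0]),  # chain rule: adjacent gaps 0.11
            ([7.00], [0]),
            ([], []),
        ],
    )
    def test_examples(self, omegas, expected):
        assert assign_groups(omegas, delta_nu=0.12) == expected

    def test_idempotent_and_contiguous(self, toy_lib):
        for comp in toy_lib.mixture.components:
            omegas = [p.omega for p in comp.peaks]
            ids = assign_groups(omegas)
            assert ids == assign_groups(omegas)
            assert sorted(set(ids)) == list(range(max(ids) + 1))

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            assign_groups([7.3, 7.0])


class TestIntegrateArea:
    def test_constant_over_default_window(self):
        grid = SpectralGrid(5.6, 9.0, 1000)
        assert integrate_area(Spectrum(grid, np.ones(1000))) == pytest.approx(3.4)

    def test_zero_spectrum(self):
        grid = SpectralGrid(5.6, 9.0, 100)
        assert integrate_area(Spectrum(grid, np.zeros(100))) == 0.0

    def test_subregion(self):
        grid = SpectralGrid(5.6, 9.0, 3401)
        area = integrate_area(Spectrum(grid, np.ones(3401)), region=(6.0, 7.0))
        assert area == pytest.approx(1.0, rel=1e-6)

    def test_region_outside_grid_raises(self):
        grid = SpectralGrid(5.6, 9.0, 100)
        with pytest.raises(ValueError):
            integrate_area(Spectrum(grid, np.ones(100)), region=(9.5, 10.0))

    def test_shift_leaves_area_unchanged(self, toy_lib):
        """Component and group shifts move interior peaks without changing area."""
        comp = toy_lib.mixture.components[1]  # peaks far from edges
        grid = toy_lib.grid
        a0 = integrate_area(Spectrum(grid, eval_component(comp, grid)))
        a1 = integrate_area(
            Spectrum(
                grid,
                eval_component(
                    comp, grid, component_shift=0.015,
                    group_shift=[0.01] * comp.n_groups,
                ),
            )
        )
        assert a1 == pytest.approx(a0, rel=0.005)
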
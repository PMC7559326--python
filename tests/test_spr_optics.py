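"""SPR optics: transfer matrix, angle features, thickness fits, De Feijter."""

import cmath

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfilm.exceptions import (ConvergenceError, FeatureNotFoundError,
                                ValidationError)
from surfilm.spr import (AngleScan, InstrumentConstants, LayerStack,
                         OpticalLayer, Sensogram, default_stack,
                         defeijter_coverage, dndc_from_tir_shift,
                         extract_plateaus, fit_layer_thickness,
                         locate_spr_minimum, locate_tir_angle,
                         reflectivity_scan, with_adlayer)
from surfilm.synthetic import gen_angle_scan, gen_titration_sensogram


def two_layer(n1, n2, wavelength=670.0):
    return LayerStack((OpticalLayer("a", n1), OpticalLayer("b", n2)), wavelength)


def airy_reflectivity(n1, n2, n3, d_nm, wavelength_nm, theta_deg):
    """Independent three-layer closed form: Fresnel + Airy summation."""
    k0 = 2 * np.pi / wavelength_nm
    kx = k0 * n1 * np.sin(np.radians(theta_deg))
    kz = [cmath.sqrt((k0 * n) ** 2 - kx ** 2) for n in (n1, n2, n3)]

    def rp(i, j, ni, nj):
        return (nj ** 2 * kz[i] - ni ** 2 * kz[j]) / (nj ** 2 * kz[i] + ni ** 2 * kz[j])

    r12, r23 = rp(0, 1, n1, n2), rp(1, 2, n2, n3)
    phase = cmath.exp(2j * kz[1] * d_nm)
    r = (r12 + r23 * phase) / (1 + r12 * r23 * phase)
    return abs(r) ** 2


class TestReflectivity:
    def test_total_internal_reflection_is_lossless(self, angle_grid):
        scan = reflectivity_scan(two_layer(1.52, 1.334), angle_grid)
        above = angle_grid > np.degrees(np.arcsin(1.334 / 1.52)) + 0.2
        assert np.allclose(scan.reflectivity[above], 1.0, atol=1e-9)

    def test_matches_three_layer_airy_closed_form(self, angle_grid):
        stack = LayerStack((OpticalLayer("glass", 1.52),
                            OpticalLayer("gold", 0.14 + 3.7j, 50.0),
                            OpticalLayer("water", 1.334)), 670.0)
        scan = reflectivity_scan(stack, angle_grid)
        oracle = np.array([airy_reflectivity(1.52, 0.14 + 3.7j, 1.334, 50.0,
                                             670.0, a) for a in angle_grid])
        assert np.abs(scan.reflectivity - oracle).max() < 1e-8

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(d_gold=st.floats(10, 80), d_extra=st.floats(0, 20),
           n_extra=st.floats(1.34, 1.6),
           wavelength=st.sampled_from([670.0, 785.0]))
    def test_passivity_for_arbitrary_stacks(self, d_gold, d_extra, n_extra,
                                            wavelength):
        stack = LayerStack((OpticalLayer("prism", 1.52),
                            OpticalLayer("gold", 0.14 + 3.7j, d_gold),
                            OpticalLayer("film", n_extra, d_extra),
                            OpticalLayer("water", 1.334)), wavelength)
        angles = np.linspace(50, 77.5, 150)
        scan = reflectivity_scan(stack, angles)
        assert scan.reflectivity.max() <= 1 + 1e-9

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValidationError):
            OpticalLayer("bad", 1.5, -1.0)

    def test_angles_outside_open_interval_rejected(self, gold_stack):
        with pytest.raises(ValidationError):
            reflectivity_scan(gold_stack, [0.0, 45.0])


class TestAngleFeatures:
    @pytest.mark.parametrize("n_medium, expected", [
        (1.334, np.degrees(np.arcsin(1.334 / 1.52))),
        (1.0, np.degrees(np.arcsin(1.0 / 1.52))),
    ])
    def test_tir_angle_matches_critical_angle(self, angle_grid, n_medium, expected):
        grid = np.arange(30.0, 77.5, 0.01) if n_medium == 1.0 else angle_grid
        scan = reflectivity_scan(two_layer(1.52, n_medium), grid)
        assert locate_tir_angle(scan) == pytest.approx(expected, abs=0.05)

    def test_flat_scan_has_no_tir(self):
        scan = AngleScan(np.linspace(50, 70, 100), np.zeros(100))
        with pytest.raises(FeatureNotFoundError):
            locate_tir_angle(scan)

    def test_minimum_interpolation_is_exact_on_parabola(self):
        x = np.linspace(67, 69.4, 25)
        scan = AngleScan(x, 0.2 + (x - 68.2) ** 2 / 10)
        assert locate_spr_minimum(scan) == pytest.approx(68.2, abs=1e-12)

    def test_adlayer_shifts_minimum_to_larger_angle(self, gold_stack, angle_grid):
        mins = []
        for d in (0.0, 2.0):
            scan = reflectivity_scan(with_adlayer(gold_stack, 1.45, d), angle_grid)
            mins.append(locate_spr_minimum(scan))
        assert mins[1] > mins[0]

    def test_boundary_minimum_warns(self):
        x = np.linspace(50, 60, 50)
        scan = AngleScan(x, np.linspace(0.1, 0.9, 50))
        with pytest.warns(UserWarning):
            locate_spr_minimum(scan)


class TestThicknessFit:
    def test_recovers_noiseless_truth(self, gold_stack, angle_grid):
        scan, truth = gen_angle_scan(gold_stack, 3.5, 1.52, noise_rel=0.0)
        d, rms = fit_layer_thickness(scan, gold_stack, 1.52)
        assert abs(d - truth["d_true_nm"]) < 1e-3
        assert rms < 1e-8

    def test_zero_thickness_recovered(self, gold_stack):
        scan, _ = gen_angle_scan(gold_stack, 0.0, 1.52)
        d, _ = fit_layer_thickness(scan, gold_stack, 1.52)
        assert d == pytest.approx(0.0, abs=1e-3)

    def test_matches_grid_search_oracle(self, gold_stack, coarse_angle_grid):
        scan, _ = gen_angle_scan(gold_stack, 7.25, 1.45,
                                 angles_deg=coarse_angle_grid)
        grid = np.linspace(0, 20, 801)
        sse = [np.sum((reflectivity_scan(with_adlayer(gold_stack, 1.45, d),
                                         coarse_angle_grid).reflectivity
                       - scan.reflectivity) ** 2) for d in grid]
        oracle = grid[int(np.argmin(sse))]
        d, _ = fit_layer_thickness(scan, gold_stack, 1.45)
        assert abs(d - oracle) <= 0.05  # within one oracle grid cell
        assert abs(d - 7.25) < 1e-3

    def test_noisy_scans_have_small_mean_bias(self, gold_stack, coarse_angle_grid):
        d_true = 3.5
        fits = []
        for rep in range(50):
            scan, _ = gen_angle_scan(gold_stack, d_true, 1.52, noise_rel=0.005,
                                     seed=1000 + rep, angles_deg=coarse_angle_grid)
            d, _ = fit_layer_thickness(scan, gold_stack, 1.52, bounds=(0, 20))
            fits.append(d)
        bias = abs(np.mean(fits) - d_true) / d_true
        assert bias < 0.05

    def test_unbracketed_minimum_raises(self, gold_stack, coarse_angle_grid):
        # target generated beyond the allowed upper bound: the misfit
        # decreases monotonically into the boundary
        scan, _ = gen_angle_scan(gold_stack, 8.0, 1.52,
                                 angles_deg=coarse_angle_grid)
        with pytest.raises(ConvergenceError):
            fit_layer_thickness(scan, gold_stack, 1.52, bounds=(0.0, 5.0))


class TestDeFeijter:
    def test_dndc_hand_arithmetic(self):
        consts = InstrumentConstants()
        val = dndc_from_tir_shift(0.1606, consts, 670.0, 0.01)
        assert val == pytest.approx(0.186, abs=0.001)

    def test_dndc_zero_shift_and_G_monotonicity(self):
        consts = InstrumentConstants()
        assert dndc_from_tir_shift(0.0, consts, 670.0, 0.01) == 0.0
        at_670 = dndc_from_tir_shift(0.1606, consts, 670.0, 0.01)
        at_785 = dndc_from_tir_shift(0.1606, consts, 785.0, 0.01)
        assert at_785 < at_670

    def test_dndc_error_paths(self):
        consts = InstrumentConstants()
        with pytest.raises(ValidationError):
            dndc_from_tir_shift(0.1, consts, 670.0, 0.0)
        with pytest.raises(ValidationError):
            dndc_from_tir_shift(0.1, consts, 800.0, 0.01)

    def test_coverage_unit_conversion_oracle(self):
        consts = InstrumentConstants()
        res = defeijter_coverage(2.0, 1.520, consts, 0.186)
        # 2e-7 cm * 0.186 / 0.186 cm^3/g = 2e-7 g/cm^2 = 200 ng/cm^2
        assert res.gamma_ng_cm2 == pytest.approx(200.0, rel=1e-9)
        assert res.optical_thickness_nm == pytest.approx(2.0 * 0.186)

    def test_coverage_linear_in_d_and_contrast(self):
        consts = InstrumentConstants()
        g1 = defeijter_coverage(2.0, 1.52, consts, 0.186).gamma_ng_cm2
        g2 = defeijter_coverage(4.0, 1.52, consts, 0.186).gamma_ng_cm2
        assert g2 == pytest.approx(2 * g1)
        ga = defeijter_coverage(2.0, 1.334 + 0.1, consts, 0.186).gamma_ng_cm2
        gb = defeijter_coverage(2.0, 1.334 + 0.2, consts, 0.186).gamma_ng_cm2
        assert gb == pytest.approx(2 * ga)

    def test_zero_thickness_zero_coverage(self):
        res = defeijter_coverage(0.0, 1.52, InstrumentConstants(), 0.186)
        assert res.gamma_ng_cm2 == 0.0

    def test_unphysical_inputs_rejected(self):
        consts = InstrumentConstants()
        with pytest.raises(ValidationError):
            defeijter_coverage(2.0, 1.52, consts, 0.0)
        with pytest.raises(ValidationError):
            defeijter_coverage(2.0, 1.30, consts, 0.186)


class TestPlateaus:
    def test_programmed_plateaus_recovered_exactly(self):
        senso, _ = gen_titration_sensogram([1.0, 2.0, 3.0], [0.05, 0.10, 0.15])
        res = extract_plateaus(senso)
        assert [p.stable for p in res] == [True] * 3
        assert [p.plateau_angle_deg for p in res] == pytest.approx(
            [0.05, 0.10, 0.15], abs=1e-3)

    def test_constant_baseline_gives_zero_plateau(self):
        senso, _ = gen_titration_sensogram([1.0], [0.0], bulk_jump_deg=0.0)
        res = extract_plateaus(senso)
        assert len(res) == 1 and res[0].plateau_angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_drifting_segment_is_flagged_not_dropped(self):
        senso, _ = gen_titration_sensogram([1.0], [0.1], drift_deg_s=0.01)
        res = extract_plateaus(senso, slope_tol_deg_s=1e-4)
        assert len(res) == 1 and not res[0].stable

    def test_marks_required(self):
        t = np.arange(0, 100.0)
        senso = Sensogram(t, np.zeros_like(t), np.full_like(t, 61.4), [])
        with pytest.raises(ValidationError):
            extract_plateaus(senso)
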
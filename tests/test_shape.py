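"""Smoothing, critical-point detection, saddle fingerprinting, shape invariance."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from arsq import (
    EEM,
    DomainError,
    ParameterError,
    SampleMeta,
    WavelengthGrid,
    classify_spectrum,
    component_eem,
    detect_saddle,
    find_critical_points,
    noiseless_sample_eem,
    shape_invariance_score,
    smooth_eem,
)
from arsq.simulate import ComponentSpectrum

from _oracles import direct_masked_convolution, neighbour_scan

META = SampleMeta(sample_id="t")


def scaled(eem, c):
    return eem.with_intensity(eem.intensity * c)


class TestSmoothing:
    def test_sigma_zero_is_identity(self, om7_eem):
        out = smooth_eem(om7_eem, 0.0)
        assert np.array_equal(out.intensity, om7_eem.intensity)

    def test_constant_preserved(self, grid):
        const = EEM.from_intensity(
            grid, np.full((grid.n_excitation, grid.n_emission), 3.5), META
        )
        out = smooth_eem(const, 2.0)
        assert np.allclose(out.valid_values(), 3.5)

    def test_delta_spike_matches_direct_convolution(self, grid):
        inten = np.zeros((grid.n_excitation, grid.n_emission))
        i = list(grid.excitation_nm).index(440.0)
        j = list(grid.emission_nm).index(560.0)
        inten[i, j] = 1.0
        eem = EEM.from_intensity(grid, inten, META)
        out = smooth_eem(eem, 1.0)
        expected = direct_masked_convolution(eem.intensity, eem.mask, 1.0)
        assert np.allclose(out.intensity[eem.mask], expected[eem.mask], atol=1e-12)

    def test_negative_sigma_rejected(self, om7_eem):
        with pytest.raises(ParameterError):
            smooth_eem(om7_eem, -1.0)

    def test_mask_preserved(self, om7_eem):
        assert np.array_equal(smooth_eem(om7_eem, 1.0).mask, om7_eem.mask)


class TestCriticalPoints:
    def test_single_bump_on_node_is_one_maximum(self):
        g = WavelengthGrid(np.arange(400.0, 551.0, 10.0), np.arange(480.0, 701.0, 10.0))
        bump = component_eem(ComponentSpectrum("b", 600.0, 30.0, 470.0, 30.0), g)
        points = find_critical_points(bump)
        assert [p.kind for p in points] == ["maximum"]
        assert (points[0].exc_nm, points[0].em_nm) == (470.0, 600.0)

    def test_two_component_surface_has_two_maxima_and_saddle(self, om7_eem):
        points = find_critical_points(om7_eem)
        kinds = sorted(p.kind for p in points)
        assert kinds == ["maximum", "maximum", "saddle"]
        maxima_em = sorted(p.em_nm for p in points if p.kind == "maximum")
        assert abs(maxima_em[0] - 500) <= 10 and abs(maxima_em[1] - 670) <= 10
        saddle = next(p for p in points if p.kind == "saddle")
        assert 520 <= saddle.em_nm <= 600

    def test_constant_surface_has_no_critical_points(self, grid):
        const = EEM.from_intensity(
            grid, np.ones((grid.n_excitation, grid.n_emission)), META
        )
        assert find_critical_points(const) == []

    def test_too_small_grid_rejected(self):
        g = WavelengthGrid(np.arange(400.0, 441.0, 10.0), np.arange(600.0, 641.0, 10.0))
        eem = EEM.from_intensity(g, np.ones((g.n_excitation, g.n_emission)), META)
        with pytest.raises(DomainError):
            find_critical_points(eem)

    def test_bad_tolerance_rejected(self, om7_eem):
        with pytest.raises(ParameterError):
            find_critical_points(om7_eem, grad_tol_frac=0.5)

    @pytest.mark.parametrize("c", [0.1, 3.0, 42.0])
    def test_scale_invariance(self, om7_eem, c):
        base = {(p.exc_nm, p.em_nm, p.kind) for p in find_critical_points(om7_eem)}
        got = {(p.exc_nm, p.em_nm, p.kind) for p in find_critical_points(scaled(om7_eem, c))}
        assert got == base


@pytest.fixture(scope="module")
def surfaces(control_eem, om7_eem, om14_eem, free_dye_eem, solved_amplitudes):
    g15 = WavelengthGrid(np.arange(400.0, 551.0, 10.0), np.arange(480.0, 701.0, 10.0))
    g31 = WavelengthGrid(np.arange(400.0, 701.0, 10.0), np.arange(440.0, 741.0, 10.0))
    two = (
        component_eem(ComponentSpectrum("p1", 520.0, 25.0, 480.0, 40.0), g31).intensity
        + 0.8
        * component_eem(ComponentSpectrum("p2", 680.0, 35.0, 560.0, 40.0), g31).intensity
    )
    return {
        "control": control_eem,
        "om_7d": om7_eem,
        "om_14d": om14_eem,
        "go_attenuated": noiseless_sample_eem(
            1.0, solved_amplitudes[3.5], attenuation=0.6
        ),
        "free_dye": free_dye_eem,
        "bump_15x23": component_eem(ComponentSpectrum("b", 600.0, 30.0, 470.0, 30.0), g15),
        "two_bumps_31x31": EEM.from_intensity(g31, two, META),
    }


class TestOracleEquivalence:
    """Hessian classifier vs exhaustive 8-neighbour scan on the same smoothed surface."""

    @pytest.mark.parametrize(
        "name",
        ["control", "om_7d", "om_14d", "go_attenuated", "free_dye",
         "bump_15x23", "two_bumps_31x31"],
    )
    def test_classifier_matches_neighbour_scan(self, surfaces, name):
        eem = surfaces[name]
        got = {(p.exc_nm, p.em_nm, p.kind) for p in find_critical_points(eem)}
        assert got == neighbour_scan(eem)


class TestSaddleDetection:
    def test_om7_saddle_in_window(self, om7_eem):
        saddle = detect_saddle(om7_eem)
        assert saddle is not None and saddle.kind == "saddle"
        assert 540 <= saddle.em_nm <= 580

    def test_free_dye_has_no_saddle(self, free_dye_eem):
        assert detect_saddle(free_dye_eem) is None

    def test_cell_only_has_no_saddle(self, control_eem):
        assert detect_saddle(control_eem) is None


class TestClassification:
    def test_cell_only_single_peak_near_500(self, control_eem):
        report = classify_spectrum(control_eem)
        assert report.classification == "undifferentiated_single_peak"
        assert not report.has_saddle and report.saddle is None
        assert abs(report.primary_peak.em_nm - 500) <= 10

    @pytest.mark.parametrize("fold", [2.0, 2.7, 3.0, 3.5])
    def test_mineralized_double_peak(self, solved_amplitudes, fold):
        eem = noiseless_sample_eem(1.0, solved_amplitudes[fold])
        report = classify_spectrum(eem)
        assert report.classification == "mineralized_double_peak"
        assert report.has_saddle and report.saddle is not None

    def test_free_dye_single_peak(self, free_dye_eem):
        report = classify_spectrum(free_dye_eem)
        assert report.classification == "free_dye_single_peak"
        assert report.primary_peak.em_nm == 670

    def test_report_record_is_flat(self, om7_eem):
        record = classify_spectrum(om7_eem).to_record("s1")
        assert record["sample_id"] == "s1"
        assert record["classification"] == "mineralized_double_peak"
        assert record["saddle_em_nm"] is not None

    def test_continuity_under_small_noise(self, om7_eem, control_eem):
        # < 1% of dynamic range must not flip has_saddle (fixed seed)
        rng = np.random.default_rng(7)
        for eem, expect in ((om7_eem, True), (control_eem, False)):
            dr = float(np.ptp(eem.valid_values()))
            for _ in range(100):
                pert = eem.with_intensity(
                    np.clip(
                        eem.intensity + 0.01 * dr * rng.standard_normal(eem.intensity.shape),
                        0.0,
                        None,
                    )
                )
                has = classify_spectrum(pert).classification == "mineralized_double_peak"
                assert has == expect

    def test_monotone_disappearance_of_saddle(self, solved_amplitudes):
        # descending complex amplitude: double peak -> single peak, no re-entry
        ladder = np.linspace(solved_amplitudes[2.0], 0.0, 15)
        seen_single = False
        for a in ladder:
            cls = classify_spectrum(noiseless_sample_eem(1.0, a)).classification
            if cls != "mineralized_double_peak":
                seen_single = True
            else:
                assert not seen_single, "saddle re-appeared on a descending ladder"
        assert seen_single


class TestShapeInvariance:
    def test_exact_scalings_score_zero(self, om7_eem):
        score = shape_invariance_score(om7_eem, [scaled(om7_eem, 3.0), scaled(om7_eem, 0.1)])
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_cell_vs_mineralized_shapes_differ(self, control_eem, om14_eem):
        score = shape_invariance_score(control_eem, [om14_eem])
        assert score > 0.2
        # direct evaluation of the normalization formula
        a = control_eem.intensity / control_eem.valid_values().max()
        b = om14_eem.intensity / om14_eem.valid_values().max()
        expected = float(np.abs(b - a)[control_eem.mask].max())
        assert score == pytest.approx(expected)

    def test_all_zero_reference_rejected(self, grid):
        zero = EEM.from_intensity(grid, np.zeros((grid.n_excitation, grid.n_emission)), META)
        with pytest.raises(DomainError):
            shape_invariance_score(zero, [zero])

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_score_zero_for_any_positive_scale(self, om7_eem, c):
        assert shape_invariance_score(om7_eem, [scaled(om7_eem, c)]) <= 1e-9
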
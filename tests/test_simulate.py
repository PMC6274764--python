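"""The synthetic twin: components, noise, substrates, amplitude solving."""

import numpy as np
import pytest

from arsq import (
    CELLULAR,
    COMPLEX,
    GLASS,
    GO,
    NoiseModel,
    ParameterError,
    ScenarioConfig,
    SpecificationError,
    component_eem,
    default_scenarios,
    generate_dilution_series,
    generate_experiment,
    generate_od,
    generate_sample_eem,
    noiseless_sample_eem,
    ratio_index,
    resolve_scenario,
    shape_invariance_score,
    solve_complex_amplitude,
)
from arsq.simulate import OD_EXTINCTION_PER_MM, _scenario_load

NOISELESS = NoiseModel(multiplicative_cv=0.0, additive_floor_frac=0.0, seed=0)


class TestComponents:
    def test_apex_is_unity_on_grid(self):
        eem = component_eem(COMPLEX)
        i = list(eem.grid.excitation_nm).index(430.0)
        j = list(eem.grid.emission_nm).index(670.0)
        assert eem.intensity[i, j] == pytest.approx(1.0)

    def test_complex_at_index_wavelengths_closed_form(self):
        # value at (420, 560) separates into excitation and emission factors
        value = float(COMPLEX.value(420.0, 560.0))
        exc_factor = np.exp(-(10.0**2) / (2 * 60.0**2))
        em_factor = np.exp(-(110.0**2) / (2 * 45.0**2))
        assert value == pytest.approx(exc_factor * em_factor, rel=1e-12)
        assert em_factor == pytest.approx(0.0504, abs=2e-4)

    def test_emission_symmetry_about_center(self):
        assert COMPLEX.value(430.0, 660.0) == pytest.approx(COMPLEX.value(430.0, 680.0))

    def test_cellular_plateau_extends_red(self):
        # the autofluorescence plateau keeps the control measurable at 670 nm
        assert CELLULAR.value(440.0, 670.0) == pytest.approx(
            CELLULAR.em_baseline_frac, rel=1e-6
        )


class TestSampleGeneration:
    def test_cell_only_noiseless_is_scaled_cellular(self):
        scenario = ScenarioConfig("control", GLASS, a_cell=1.7, a_complex=0.0)
        eem = generate_sample_eem(scenario, NOISELESS)
        expected = 1.7 * component_eem(CELLULAR).intensity
        assert np.allclose(eem.intensity[eem.mask], expected[eem.mask])

    def test_same_seed_reproduces(self):
        scenario = ScenarioConfig("om_7d", GLASS, a_complex=0.12)
        noise = NoiseModel(seed=5)
        a = generate_sample_eem(scenario, noise, replicate=2)
        b = generate_sample_eem(scenario, noise, replicate=2)
        assert np.array_equal(a.intensity, b.intensity)
        c = generate_sample_eem(scenario, NoiseModel(seed=6), replicate=2)
        assert not np.array_equal(a.intensity, c.intensity)

    def test_opaque_substrate_is_scalar_attenuation(self):
        glass = generate_sample_eem(ScenarioConfig("om_7d", GLASS, a_complex=0.2), NOISELESS)
        go = generate_sample_eem(ScenarioConfig("go_7d", GO, a_complex=0.2), NOISELESS)
        assert np.allclose(go.intensity[go.mask], 0.6 * glass.intensity[glass.mask])
        assert ratio_index(go).value == pytest.approx(ratio_index(glass).value, rel=1e-12)

    def test_unresolved_amplitude_rejected(self):
        scenario = ScenarioConfig("om_7d", GLASS, a_complex="solve_for_fold", target_fold=2.0)
        with pytest.raises(SpecificationError):
            generate_sample_eem(scenario, NOISELESS)


class TestODGeneration:
    def test_zero_load_flat_baseline(self):
        od = generate_od(0.0, GLASS, NOISELESS)
        assert np.allclose(od.od, 0.02)

    def test_linearity_in_load(self):
        lo = generate_od(0.5, GLASS, NOISELESS)
        hi = generate_od(1.0, GLASS, NOISELESS)
        assert (hi.at(515.0) - 0.02) == pytest.approx(2 * (lo.at(515.0) - 0.02))

    def test_opaque_substrate_swamps_ars_signal(self):
        scenario = resolve_scenario(
            ScenarioConfig("go_7d", GO, a_complex="solve_for_fold", target_fold=2.7)
        )
        load = _scenario_load(scenario)
        od = generate_od(load, GO, NOISELESS)
        ars_part = OD_EXTINCTION_PER_MM * load
        assert ars_part / od.at(515.0) < 0.05  # unusable in situ: flagged by caller

    def test_negative_load_rejected(self):
        with pytest.raises(ParameterError):
            generate_od(-0.1, GLASS, NOISELESS)


class TestDilutionSeries:
    def test_noiseless_members_scale_rigidly(self):
        series = generate_dilution_series([0.25, 1.0, 4.0], noise=NOISELESS)
        ref = series.samples[0][0]
        others = [eem for eem, _ in series.samples[1:]]
        assert shape_invariance_score(ref, others) == pytest.approx(0.0, abs=1e-12)

    def test_f670_ratio_matches_concentration_ratio(self):
        from arsq import get_intensity

        series = generate_dilution_series([0.25, 1.0, 4.0], noise=NOISELESS)
        f = [get_intensity(eem, 420.0, 670.0) for eem, _ in series.samples]
        assert f[2] / f[0] == pytest.approx(16.0, rel=1e-12)

    def test_no_member_has_a_saddle(self):
        from arsq import detect_saddle

        series = generate_dilution_series([0.25, 1.0, 4.0], noise=NOISELESS)
        for eem, _ in series.samples:
            assert detect_saddle(eem) is None

    def test_non_positive_concentration_rejected(self):
        with pytest.raises(ParameterError):
            generate_dilution_series([0.0, 1.0], noise=NOISELESS)


class TestAmplitudeSolver:
    def test_fold_one_is_zero_amplitude(self):
        assert solve_complex_amplitude(1.0) == 0.0

    def test_self_consistency(self):
        base = ratio_index(noiseless_sample_eem(1.0, 0.0)).value
        a = solve_complex_amplitude(2.7)
        realized = ratio_index(noiseless_sample_eem(1.0, a)).value / base
        assert realized == pytest.approx(2.7, abs=1e-6)

    def test_agrees_with_grid_search_oracle(self):
        target = 3.0
        base = ratio_index(noiseless_sample_eem(1.0, 0.0)).value
        a_bisect = solve_complex_amplitude(target)

        # independent dense grid search, refined twice around the best cell
        lo, hi = 0.0, 1.0
        for _ in range(3):
            grid_a = np.linspace(lo, hi, 501)
            errs = [
                abs(ratio_index(noiseless_sample_eem(1.0, a)).value / base - target)
                for a in grid_a
            ]
            k = int(np.argmin(errs))
            lo, hi = grid_a[max(k - 1, 0)], grid_a[min(k + 1, len(grid_a) - 1)]
        a_grid = 0.5 * (lo + hi)
        assert a_bisect == pytest.approx(a_grid, rel=1e-4)  # 4 significant digits

    def test_target_below_one_rejected(self):
        with pytest.raises(ParameterError):
            solve_complex_amplitude(0.5)

    @pytest.mark.parametrize("fold", [2.0, 2.7, 3.5])
    def test_noiseless_emission_minimum_near_saddle_wavelength(self, fold):
        # brute-force scan of the 420 nm excitation slice: the minimum
        # between the two emission lobes must land within 560 +/- 10 nm
        eem = noiseless_sample_eem(1.0, solve_complex_amplitude(fold))
        i = list(eem.grid.excitation_nm).index(420.0)
        em = eem.grid.emission_nm[eem.mask[i]]
        profile = eem.intensity[i][eem.mask[i]]
        sel = (em >= 500) & (em <= 650)
        em_min = em[sel][np.argmin(profile[sel])]
        assert abs(em_min - 560.0) <= 10.0


class TestExperiment:
    def test_cardinality_and_files(self, tmp_path):
        out = tmp_path / "exp"
        manifest, measurements = generate_experiment(
            default_scenarios(3), NoiseModel(seed=1), out_dir=out
        )
        # 3 blanks + 5 scenarios x 3 replicates x 2 rows (surface, liquid)
        assert len(manifest) == 3 + 5 * 3 * 2
        eem_files = list(out.glob("eem_*.csv"))
        od_files = list(out.glob("od_*.csv"))
        assert len(eem_files) == 3 + 30 and len(od_files) == 3 + 30
        assert (out / "manifest.csv").exists() and (out / "ground_truth.csv").exists()

    def test_control_extract_mirrors_cellular_shape(self):
        _, measurements = generate_experiment(default_scenarios(1), NOISELESS)
        liquid_ctrl = next(
            m.eem
            for m in measurements
            if m.meta.condition == "control" and m.meta.mode == "liquid"
        )
        # no complex term: the extract is a scalar multiple of the cellular EEM
        cellular = component_eem(CELLULAR)
        assert shape_invariance_score(cellular, [liquid_ctrl]) == pytest.approx(0.0, abs=1e-9)

    def test_missing_control_rejected(self):
        scenarios = [s for s in default_scenarios(1) if s.condition != "control"]
        with pytest.raises(SpecificationError):
            generate_experiment(scenarios, NOISELESS)

    def test_byte_identical_per_seed(self, tmp_path):
        dirs = []
        for name in ("a", "b"):
            out = tmp_path / name
            generate_experiment(default_scenarios(2), NoiseModel(seed=3), out_dir=out)
            dirs.append(out)
        files = sorted(p.name for p in dirs[0].iterdir())
        assert files == sorted(p.name for p in dirs[1].iterdir())
        for name in files:
            assert (dirs[0] / name).read_bytes() == (dirs[1] / name).read_bytes(), name
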
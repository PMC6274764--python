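"""Seeded synthetic twin of the mineralization assay.

No raw spectra are deposited with the study this package models, so all
pipelines are exercised on a generative twin with known ground truth.  Three
fluorophore populations are modelled as separable excitation x emission
profiles:

``cellular``
    autofluorescence of undifferentiated cells: a 500 nm emission peak on a
    broad low plateau (the plateau stands for the wideband autofluorescence
    background that real cell layers show out to the red; without it a
    ratio of red to green intensities in the control would be vanishingly
    small and unmeasurable).
``complex``
    the ARS-calcium complex of mineralized matrix: emission peak at 670 nm.
    Its growth against the cellular profile creates the diagnostic saddle
    near 560 nm emission.
``free_ars``
    unbound dye in solution: a single 670 nm emission component, so dilution
    series scale rigidly with concentration.

Substrates modify the optics only: glass is transparent, graphene oxide
adds a large broadband absorbance baseline (which makes in-situ OD useless)
while attenuating fluorescence by a wavelength-independent scalar.

All randomness is drawn from streams keyed by ``(seed, sample_id,
replicate)``, so identical seeds reproduce identical files byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .eem import (
    EEM,
    DilutionSeries,
    ODSpectrum,
    SampleMeta,
    WavelengthGrid,
    write_eem_csv,
    write_od_csv,
)
from .errors import ParameterError, SpecificationError
from .quantify import DEFAULT_INDEX, IndexDefinition, ratio_index

# ---------------------------------------------------------------------------
# Component and instrument models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentSpectrum:
    """Separable excitation x emission profile of one fluorophore population.

    intensity(exc, em) = exp(-(exc - exc_center)^2 / (2 exc_sigma^2))
                       * (exp(-(em - em_center)^2 / (2 em_sigma^2)) + em_baseline_frac)

    ``em_baseline_frac`` adds a flat emission plateau (fraction of the
    emission-Gaussian apex); it is zero for the dye components and non-zero
    for cellular autofluorescence.
    """

    name: str
    em_center_nm: float
    em_sigma_nm: float
    exc_center_nm: float
    exc_sigma_nm: float
    em_baseline_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.em_sigma_nm <= 0 or self.exc_sigma_nm <= 0:
            raise ParameterError("component sigmas must be positive")
        if self.em_baseline_frac < 0:
            raise ParameterError("emission baseline fraction must be non-negative")

    def value(self, exc_nm, em_nm):
        exc_nm = np.asarray(exc_nm, dtype=float)
        em_nm = np.asarray(em_nm, dtype=float)
        exc_part = np.exp(-((exc_nm - self.exc_center_nm) ** 2) / (2 * self.exc_sigma_nm**2))
        em_part = (
            np.exp(-((em_nm - self.em_center_nm) ** 2) / (2 * self.em_sigma_nm**2))
            + self.em_baseline_frac
        )
        return exc_part * em_part


#: Default components.  Peak positions follow the assay (500 nm cellular,
#: 670 nm complex/dye); widths and the cellular plateau are model choices
#: tuned so that (a) the two-component surface forms its emission minimum at
#: 420 nm excitation within 560 +/- 10 nm for the study fold range and
#: (b) the control's 670/560 ratio stays well above the instrument noise
#: floor.  See docs/methods.md.
CELLULAR = ComponentSpectrum("cellular", 500.0, 18.0, 440.0, 50.0, em_baseline_frac=0.12)
COMPLEX = ComponentSpectrum("complex", 670.0, 45.0, 430.0, 60.0)
FREE_ARS = ComponentSpectrum("free_ars", 670.0, 50.0, 430.0, 60.0)


@dataclass(frozen=True)
class NoiseModel:
    """Instrument noise: multiplicative CV plus a folded-normal additive floor.

    The additive floor is expressed as a fraction of the instrument full
    scale (1 a.u., the amplitude of one unit of cellular signal), not of the
    individual sample's maximum: detector noise does not scale with the
    specimen.  Each stored spectrum is the average of
    ``readings_per_spectrum`` independent instrument readings, mirroring the
    acquisition protocol (three spectral readings averaged per measurement).
    Identical seeds give identical output.
    """

    multiplicative_cv: float = 0.02
    additive_floor_frac: float = 0.005
    seed: int = 0
    readings_per_spectrum: int = 3

    def __post_init__(self) -> None:
        if self.multiplicative_cv < 0 or self.additive_floor_frac < 0:
            raise ParameterError("noise parameters must be non-negative")
        if self.readings_per_spectrum < 1:
            raise ParameterError("readings_per_spectrum must be >= 1")


#: Full-scale intensity (a.u.) that the additive noise floor refers to.
FULL_SCALE_AU = 1.0


@dataclass(frozen=True)
class SubstrateModel:
    """Optical behaviour of the support: absorbance baseline + scalar attenuation."""

    kind: str
    od_baseline: float
    fluor_attenuation: float

    def __post_init__(self) -> None:
        if not (0 < self.fluor_attenuation <= 1):
            raise ParameterError("fluorescence attenuation must lie in (0, 1]")
        if self.od_baseline < 0:
            raise ParameterError("OD baseline must be non-negative")


GLASS = SubstrateModel("glass", od_baseline=0.02, fluor_attenuation=1.0)
GO = SubstrateModel("go", od_baseline=2.0, fluor_attenuation=0.6)
SOLUTION = SubstrateModel("solution", od_baseline=0.04, fluor_attenuation=1.0)

_SUBSTRATES = {"glass": GLASS, "go": GO, "solution": SOLUTION}

# Absorbance model: OD(lambda) = baseline + OD_EXTINCTION_PER_MM * load * g(lambda)
# with g a Gaussian peaked at 515 nm.  "load" is the ARS amount in
# mM-equivalents: free dye contributes its concentration; stained cultures
# contribute a background (nonspecific) staining term per unit cellular
# amplitude plus a term per unit of bound-complex amplitude.
OD_EXTINCTION_PER_MM = 0.15
OD_PEAK_CENTER_NM = 515.0
OD_PEAK_SIGMA_NM = 40.0
BACKGROUND_LOAD_PER_CELL = 0.2
LOAD_PER_COMPLEX = 1.55
OD_WAVELENGTHS = np.arange(400.0, 701.0, 5.0)

#: Fraction of the cellular-associated signal carried into the acid extract
#: together with the dye (soluble autofluorescent species + nonspecifically
#: bound dye); keeps the extract's spectral composition proportional to the
#: surface composition.
EXTRACT_BACKGROUND_FRAC = 1.0
#: Lognormal standard deviation of the per-replicate extraction efficiency.
EXTRACTION_JITTER_SD = 0.02


@dataclass
class ScenarioConfig:
    """Generative ground truth for one experimental condition."""

    condition: str
    substrate: SubstrateModel = GLASS
    a_cell: float = 1.0
    a_complex: Union[float, str] = 0.0  # number or "solve_for_fold"
    target_fold: Optional[float] = None
    extraction_efficiency: float = 0.9
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.a_complex == "solve_for_fold" and self.target_fold is None:
            raise SpecificationError(
                f"{self.condition}: target_fold required when a_complex is solved"
            )
        if not (0 < self.extraction_efficiency <= 1):
            raise ParameterError("extraction efficiency must lie in (0, 1]")
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")


def default_scenarios(replicates: int = 3) -> List[ScenarioConfig]:
    """The five study conditions.

    The graphene-oxide fold inductions (2.7 without and 3.5 with osteogenic
    medium) are the study's reported values; the glass osteogenic-medium
    folds (2.0 at day 7, 3.0 at day 14) are free model choices since no
    numeric values are printed for them.
    """
    return [
        ScenarioConfig("control", GLASS, a_complex=0.0, target_fold=1.0,
                       replicates=replicates),
        ScenarioConfig("om_7d", GLASS, a_complex="solve_for_fold", target_fold=2.0,
                       replicates=replicates),
        ScenarioConfig("om_14d", GLASS, a_complex="solve_for_fold", target_fold=3.0,
                       replicates=replicates),
        ScenarioConfig("go_7d", GO, a_complex="solve_for_fold", target_fold=2.7,
                       replicates=replicates),
        ScenarioConfig("go_om_7d", GO, a_complex="solve_for_fold", target_fold=3.5,
                       replicates=replicates),
    ]


# ---------------------------------------------------------------------------
# RNG plumbing
# ---------------------------------------------------------------------------


def _rng(seed: int, sample_id: str, replicate: int = 0) -> np.random.Generator:
    """Deterministic per-sample stream keyed by (seed, sample_id, replicate)."""
    key = zlib.crc32(sample_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key, replicate]))


def _apply_eem_noise(intensity: np.ndarray, mask: np.ndarray, noise: NoiseModel,
                     rng: np.random.Generator) -> np.ndarray:
    if noise.multiplicative_cv == 0 and noise.additive_floor_frac == 0:
        return intensity
    acc = np.zeros_like(intensity)
    for _ in range(noise.readings_per_spectrum):
        mult = 1.0 + noise.multiplicative_cv * rng.standard_normal(intensity.shape)
        floor = noise.additive_floor_frac * FULL_SCALE_AU * np.abs(
            rng.standard_normal(intensity.shape)
        )
        acc += np.clip(intensity * mult + floor, 0.0, None)
    return np.where(mask, acc / noise.readings_per_spectrum, 0.0)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def component_eem(
    component: ComponentSpectrum,
    grid: Optional[WavelengthGrid] = None,
    meta: Optional[SampleMeta] = None,
) -> EEM:
    """Unit-amplitude EEM of one component on a grid."""
    grid = grid or WavelengthGrid.default()
    meta = meta or SampleMeta(sample_id=f"component_{component.name}",
                              condition="blank", substrate="solution")
    intensity = component.value(grid.excitation_nm[:, None], grid.emission_nm[None, :])
    return EEM.from_intensity(grid, intensity, meta)


def _composite_intensity(
    grid: WavelengthGrid,
    a_cell: float,
    a_complex: float,
    cellular: ComponentSpectrum = CELLULAR,
    complex_: ComponentSpectrum = COMPLEX,
) -> np.ndarray:
    exc = grid.excitation_nm[:, None]
    em = grid.emission_nm[None, :]
    return a_cell * cellular.value(exc, em) + a_complex * complex_.value(exc, em)


def noiseless_sample_eem(
    a_cell: float,
    a_complex: float,
    grid: Optional[WavelengthGrid] = None,
    attenuation: float = 1.0,
    meta: Optional[SampleMeta] = None,
    cellular: ComponentSpectrum = CELLULAR,
    complex_: ComponentSpectrum = COMPLEX,
) -> EEM:
    """Noise-free two-component surface (for oracles and amplitude solving)."""
    grid = grid or WavelengthGrid.default()
    meta = meta or SampleMeta(sample_id="noiseless", condition="control")
    intensity = attenuation * _composite_intensity(grid, a_cell, a_complex,
                                                   cellular, complex_)
    return EEM.from_intensity(grid, intensity, meta)


def generate_sample_eem(
    scenario: ScenarioConfig,
    noise: NoiseModel,
    grid: Optional[WavelengthGrid] = None,
    replicate: int = 1,
    cellular: ComponentSpectrum = CELLULAR,
    complex_: ComponentSpectrum = COMPLEX,
) -> EEM:
    """Seeded noisy surface EEM for one scenario replicate."""
    if scenario.a_complex == "solve_for_fold":
        raise SpecificationError(
            f"{scenario.condition}: a_complex must be resolved (numeric) before generation"
        )
    grid = grid or WavelengthGrid.default()
    meta = SampleMeta(
        sample_id=f"{scenario.condition}_r{replicate}_surface",
        condition=scenario.condition,
        substrate=scenario.substrate.kind,
        mode="surface",
        replicate=replicate,
    )
    clean = scenario.substrate.fluor_attenuation * _composite_intensity(
        grid, scenario.a_cell, float(scenario.a_complex), cellular, complex_
    )
    mask = grid.scatter_mask()
    rng = _rng(noise.seed, meta.sample_id, replicate)
    noisy = _apply_eem_noise(np.where(mask, clean, 0.0), mask, noise, rng)
    return EEM(grid=grid, intensity=noisy, mask=mask, meta=meta)


def generate_blank_eem(
    substrate: SubstrateModel,
    noise: NoiseModel,
    grid: Optional[WavelengthGrid] = None,
    replicate: int = 1,
) -> EEM:
    """Negative-control EEM (empty slide/well): additive instrument floor only."""
    grid = grid or WavelengthGrid.default()
    meta = SampleMeta(
        sample_id=f"blank_{substrate.kind}_r{replicate}",
        condition="blank",
        substrate=substrate.kind,
        mode="liquid" if substrate.kind == "solution" else "surface",
        replicate=replicate,
    )
    mask = grid.scatter_mask()
    rng = _rng(noise.seed, meta.sample_id, replicate)
    intensity = _apply_eem_noise(
        np.zeros((grid.n_excitation, grid.n_emission)), mask, noise, rng
    )
    return EEM(grid=grid, intensity=intensity, mask=mask, meta=meta)


def generate_od(
    load_mM: float,
    substrate: SubstrateModel,
    noise: NoiseModel,
    meta: Optional[SampleMeta] = None,
    wavelengths_nm: np.ndarray = OD_WAVELENGTHS,
    rng: Optional[np.random.Generator] = None,
) -> ODSpectrum:
    """Absorbance spectrum for an ARS load (mM-equivalents) on a substrate."""
    if load_mM < 0:
        raise ParameterError("ARS load must be non-negative")
    meta = meta or SampleMeta(sample_id="od", condition="blank",
                              substrate=substrate.kind)
    g = np.exp(-((wavelengths_nm - OD_PEAK_CENTER_NM) ** 2) / (2 * OD_PEAK_SIGMA_NM**2))
    od = substrate.od_baseline + OD_EXTINCTION_PER_MM * load_mM * g
    if noise.multiplicative_cv > 0:
        rng = rng if rng is not None else _rng(noise.seed, meta.sample_id, meta.replicate)
        readings = [
            np.clip(od * (1.0 + noise.multiplicative_cv * rng.standard_normal(od.shape)),
                    0.0, None)
            for _ in range(noise.readings_per_spectrum)
        ]
        od = np.mean(readings, axis=0)
    return ODSpectrum(wavelength_nm=wavelengths_nm.copy(), od=np.clip(od, 0.0, None),
                      meta=meta)


def default_dilution_ladder() -> np.ndarray:
    """12-point geometric ladder spanning 0.00125-4 mM (near two-fold steps)."""
    return np.geomspace(0.00125, 4.0, 12)


def generate_dilution_series(
    concentrations_mM: Optional[Sequence[float]] = None,
    noise: NoiseModel = NoiseModel(),
    grid: Optional[WavelengthGrid] = None,
    free_ars: ComponentSpectrum = FREE_ARS,
) -> DilutionSeries:
    """Free-dye dilution series: rigidly scaling EEMs and matched OD spectra."""
    conc = np.asarray(
        default_dilution_ladder() if concentrations_mM is None else concentrations_mM,
        dtype=float,
    )
    if np.any(conc <= 0):
        raise ParameterError("dilution concentrations must be positive")
    grid = grid or WavelengthGrid.default()
    base = component_eem(free_ars, grid).intensity
    mask = grid.scatter_mask()
    samples = []
    for k, c in enumerate(conc):
        meta = SampleMeta(
            sample_id=f"free_ars_{k}",
            condition="free_ars",
            substrate="solution",
            mode="liquid",
            concentration_mM=float(c),
        )
        rng = _rng(noise.seed, meta.sample_id, 1)
        noisy = _apply_eem_noise(np.where(mask, c * base, 0.0), mask, noise, rng)
        eem = EEM(grid=grid, intensity=noisy, mask=mask, meta=meta)
        od = generate_od(float(c), SOLUTION, noise, meta=meta, rng=rng)
        samples.append((eem, od))
    return DilutionSeries(concentrations_mM=conc, samples=samples)


# ---------------------------------------------------------------------------
# Amplitude solving
# ---------------------------------------------------------------------------


def solve_complex_amplitude(
    target_fold: float,
    a_cell: float = 1.0,
    grid: Optional[WavelengthGrid] = None,
    cellular: ComponentSpectrum = CELLULAR,
    complex_: ComponentSpectrum = COMPLEX,
    index_definition: IndexDefinition = DEFAULT_INDEX,
    rel_tol: float = 1e-9,
) -> float:
    """Complex amplitude whose noiseless ratio index is ``target_fold`` x control's.

    The map a_complex -> index is strictly increasing (the 670 nm numerator
    grows ~20x faster than the 560 nm denominator), so bisection converges.
    """
    if target_fold < 1:
        raise ParameterError("target fold must be >= 1")
    grid = grid or WavelengthGrid.default()

    def index_of(a: float) -> float:
        eem = noiseless_sample_eem(a_cell, a, grid, cellular=cellular, complex_=complex_)
        return ratio_index(eem, index_definition).value

    base = index_of(0.0)
    target = target_fold * base
    if target_fold == 1:
        return 0.0
    lo, hi = 0.0, max(a_cell, 1.0)
    while index_of(hi) < target:
        hi *= 2.0
        if hi > 1e9:
            raise ParameterError("target fold unreachable with this component model")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if index_of(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo <= rel_tol * max(hi, 1e-12):
            break
    return 0.5 * (lo + hi)


def resolve_scenario(scenario: ScenarioConfig,
                     grid: Optional[WavelengthGrid] = None) -> ScenarioConfig:
    """Return a copy with a numeric a_complex (solving for the target fold)."""
    if scenario.a_complex != "solve_for_fold":
        return scenario
    a = solve_complex_amplitude(scenario.target_fold, scenario.a_cell, grid)
    return replace(scenario, a_complex=a)


# ---------------------------------------------------------------------------
# Full experiments
# ---------------------------------------------------------------------------


def _scenario_load(scenario: ScenarioConfig) -> float:
    """ARS load (mM-equivalents) of a stained culture."""
    return (
        BACKGROUND_LOAD_PER_CELL * scenario.a_cell
        + LOAD_PER_COMPLEX * float(scenario.a_complex)
    )


def generate_experiment(
    scenarios: Sequence[ScenarioConfig],
    noise: NoiseModel,
    grid: Optional[WavelengthGrid] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> Tuple[pd.DataFrame, List]:
    """Generate a full multi-condition experiment.

    For every scenario and replicate, four measurements are produced: a
    surface EEM, a surface OD spectrum, a liquid (extract) EEM and a liquid
    OD spectrum, plus blanks per substrate and a solution blank.  When
    ``out_dir`` is given, all spectra are written as CSV together with a
    manifest and a ground-truth sidecar.

    Returns ``(manifest DataFrame, list of Measurement-like records)`` where
    each record is ``(SampleMeta, EEM or None, ODSpectrum or None)`` packed
    as :class:`arsq.quantify.Measurement`.
    """
    from .quantify import Measurement  # local import to avoid cycles at import time

    if not any(s.condition == "control" for s in scenarios):
        raise SpecificationError("experiment requires a control scenario")
    grid = grid or WavelengthGrid.default()
    mask = grid.scatter_mask()
    resolved = [resolve_scenario(s, grid) for s in scenarios]

    measurements: List[Measurement] = []
    rows: List[dict] = []
    truth_rows: List[dict] = []

    def add(meta: SampleMeta, eem: Optional[EEM], od: Optional[ODSpectrum]) -> None:
        measurements.append(Measurement(meta=meta, eem=eem, od=od))
        rows.append(
            {
                "sample_id": meta.sample_id,
                "condition": meta.condition,
                "substrate": meta.substrate,
                "mode": meta.mode,
                "replicate": meta.replicate,
                "concentration_mM": meta.concentration_mM,
                "eem_path": f"eem_{meta.sample_id}.csv" if eem is not None else "",
                "od_path": f"od_{meta.sample_id}.csv" if od is not None else "",
            }
        )

    # blanks: one EEM + one OD per substrate in use, plus the solution blank
    substrates = {s.substrate.kind for s in resolved} | {"solution"}
    for kind in sorted(substrates):
        sub = _SUBSTRATES[kind]
        meta = SampleMeta(
            sample_id=f"blank_{kind}",
            condition="blank",
            substrate=kind,
            mode="liquid" if kind == "solution" else "surface",
        )
        rng = _rng(noise.seed, meta.sample_id, 1)
        blank_eem = EEM(
            grid=grid,
            intensity=_apply_eem_noise(np.zeros((grid.n_excitation, grid.n_emission)),
                                       mask, noise, rng),
            mask=mask.copy(),
            meta=meta,
        )
        blank_od = generate_od(0.0, sub, noise, meta=meta, rng=rng)
        add(meta, blank_eem, blank_od)

    for scenario in resolved:
        a_complex = float(scenario.a_complex)
        truth_rows.append(
            {
                "condition": scenario.condition,
                "a_cell": scenario.a_cell,
                "a_complex": a_complex,
                "target_fold": scenario.target_fold,
                "attenuation": scenario.substrate.fluor_attenuation,
                "extraction_efficiency": scenario.extraction_efficiency,
            }
        )
        load = _scenario_load(scenario)
        for r in range(1, scenario.replicates + 1):
            # ---- surface (in situ) -------------------------------------
            surf_eem = generate_sample_eem(scenario, noise, grid, replicate=r)
            surf_od_meta = SampleMeta(
                sample_id=f"{scenario.condition}_r{r}_surface",
                condition=scenario.condition,
                substrate=scenario.substrate.kind,
                mode="surface",
                replicate=r,
            )
            rng_od = _rng(noise.seed, surf_od_meta.sample_id + "_od", r)
            surf_od = generate_od(load, scenario.substrate, noise,
                                  meta=surf_od_meta, rng=rng_od)
            add(surf_od_meta, surf_eem, surf_od)

            # ---- liquid (acid extract, measured in a clear well) -------
            liq_meta = SampleMeta(
                sample_id=f"{scenario.condition}_r{r}_liquid",
                condition=scenario.condition,
                substrate="solution",
                mode="liquid",
                replicate=r,
            )
            rng_liq = _rng(noise.seed, liq_meta.sample_id, r)
            eff = scenario.extraction_efficiency * float(
                np.exp(EXTRACTION_JITTER_SD * rng_liq.standard_normal())
            )
            liq_clean = eff * _composite_intensity(
                grid, EXTRACT_BACKGROUND_FRAC * scenario.a_cell, a_complex
            )
            liq_eem = EEM(
                grid=grid,
                intensity=_apply_eem_noise(np.where(mask, liq_clean, 0.0), mask,
                                           noise, rng_liq),
                mask=mask.copy(),
                meta=liq_meta,
            )
            liq_od = generate_od(eff * load, SOLUTION, noise, meta=liq_meta,
                                 rng=rng_liq)
            add(liq_meta, liq_eem, liq_od)

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for m in measurements:
            if m.eem is not None:
                write_eem_csv(m.eem, out / f"eem_{m.meta.sample_id}.csv")
            if m.od is not None:
                write_od_csv(m.od, out / f"od_{m.meta.sample_id}.csv")
        manifest.to_csv(out / "manifest.csv", index=False)
        pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    return manifest, measurements
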
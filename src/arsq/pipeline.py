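"""File-level orchestration: manifests, analysis runs and report tables.

Every run writes CSV reports plus a JSON log recording the seed and every
default parameter actually used, so a run can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import simulate
from .calibration import calibrate_fluorescence, calibrate_od, cross_calibrate
from .eem import (
    DilutionSeries,
    SampleMeta,
    read_eem_csv,
    read_od_csv,
    subtract_background,
)
from .errors import SpecificationError
from .quantify import Measurement, quantify_condition
from .shape import classify_spectrum
from .simulate import NoiseModel, ScenarioConfig, default_scenarios, generate_experiment

_MANIFEST_COLUMNS = (
    "sample_id",
    "condition",
    "substrate",
    "mode",
    "replicate",
    "concentration_mM",
    "eem_path",
    "od_path",
)


def _defaults_log(noise: NoiseModel, seed: int, extra: Optional[dict] = None) -> dict:
    log = {
        "seed": seed,
        "noise": dataclasses.asdict(noise),
        "components": {
            c.name: dataclasses.asdict(c)
            for c in (simulate.CELLULAR, simulate.COMPLEX, simulate.FREE_ARS)
        },
        "substrates": {
            s.kind: dataclasses.asdict(s)
            for s in (simulate.GLASS, simulate.GO, simulate.SOLUTION)
        },
        "od_model": {
            "extinction_per_mM": simulate.OD_EXTINCTION_PER_MM,
            "peak_center_nm": simulate.OD_PEAK_CENTER_NM,
            "peak_sigma_nm": simulate.OD_PEAK_SIGMA_NM,
            "background_load_per_cell": simulate.BACKGROUND_LOAD_PER_CELL,
            "load_per_complex": simulate.LOAD_PER_COMPLEX,
        },
        "extraction": {
            "background_frac": simulate.EXTRACT_BACKGROUND_FRAC,
            "jitter_sd": simulate.EXTRACTION_JITTER_SD,
        },
    }
    if extra:
        log.update(extra)
    return log


def _write_log(out_dir: Path, payload: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run_log.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_manifest(manifest_path) -> List[Measurement]:
    """Load every sample listed in a manifest CSV (paths relative to it)."""
    manifest_path = Path(manifest_path)
    try:
        df = pd.read_csv(manifest_path, keep_default_na=False)
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise SpecificationError(f"cannot read manifest {manifest_path}: {exc}") from exc
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SpecificationError(f"{manifest_path}: manifest missing columns {missing}")
    base = manifest_path.parent
    measurements: List[Measurement] = []
    for _, row in df.iterrows():
        conc = row["concentration_mM"]
        meta = SampleMeta(
            sample_id=str(row["sample_id"]),
            condition=str(row["condition"]),
            substrate=str(row["substrate"]),
            mode=str(row["mode"]),
            replicate=int(row["replicate"]),
            concentration_mM=float(conc) if str(conc) != "" else None,
        )
        eem = read_eem_csv(base / row["eem_path"], meta) if row["eem_path"] else None
        od = read_od_csv(base / row["od_path"], meta) if row["od_path"] else None
        measurements.append(Measurement(meta=meta, eem=eem, od=od))
    return measurements


def series_from_measurements(measurements: Sequence[Measurement]) -> DilutionSeries:
    """Rebuild a DilutionSeries from free-dye measurements."""
    stained = [
        m for m in measurements if m.meta.condition == "free_ars" and m.eem is not None
    ]
    if len(stained) < 3:
        raise SpecificationError("dilution series needs at least 3 free-dye samples")
    stained.sort(key=lambda m: m.meta.concentration_mM)
    return DilutionSeries(
        concentrations_mM=np.array([m.meta.concentration_mM for m in stained]),
        samples=[(m.eem, m.od) for m in stained],
    )


def run_simulate(
    out_dir,
    seed: int,
    scenarios: Optional[Sequence[ScenarioConfig]] = None,
    replicates: int = 3,
    multiplicative_cv: float = 0.02,
    additive_floor_frac: float = 0.005,
) -> Path:
    """Generate the default experiment plus a dilution series under out_dir."""
    out = Path(out_dir)
    noise = NoiseModel(multiplicative_cv=multiplicative_cv,
                       additive_floor_frac=additive_floor_frac, seed=seed)
    scenarios = list(scenarios) if scenarios is not None else default_scenarios(replicates)
    generate_experiment(scenarios, noise, out_dir=out / "experiment")

    series = simulate.generate_dilution_series(noise=noise)
    series_dir = out / "dilution"
    series_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (eem, od), conc in zip(series.samples, series.concentrations_mM):
        from .eem import write_eem_csv, write_od_csv

        write_eem_csv(eem, series_dir / f"eem_{eem.meta.sample_id}.csv")
        write_od_csv(od, series_dir / f"od_{eem.meta.sample_id}.csv")
        rows.append(
            {
                "sample_id": eem.meta.sample_id,
                "condition": "free_ars",
                "substrate": "solution",
                "mode": "liquid",
                "replicate": 1,
                "concentration_mM": conc,
                "eem_path": f"eem_{eem.meta.sample_id}.csv",
                "od_path": f"od_{eem.meta.sample_id}.csv",
            }
        )
    blank_meta = SampleMeta(sample_id="blank_solution", condition="blank",
                            substrate="solution", mode="liquid")
    blank_od = simulate.generate_od(0.0, simulate.SOLUTION, noise, meta=blank_meta)
    from .eem import write_od_csv

    write_od_csv(blank_od, series_dir / "od_blank_solution.csv")
    rows.append(
        {
            "sample_id": "blank_solution",
            "condition": "blank",
            "substrate": "solution",
            "mode": "liquid",
            "replicate": 1,
            "concentration_mM": "",
            "eem_path": "",
            "od_path": "od_blank_solution.csv",
        }
    )
    pd.DataFrame(rows).to_csv(series_dir / "manifest.csv", index=False)

    _write_log(
        out,
        _defaults_log(
            noise,
            seed,
            {
                "command": "simulate",
                "scenarios": [
                    {
                        "condition": s.condition,
                        "substrate": s.substrate.kind,
                        "a_cell": s.a_cell,
                        "a_complex": s.a_complex
                        if isinstance(s.a_complex, str)
                        else float(s.a_complex),
                        "target_fold": s.target_fold,
                        "replicates": s.replicates,
                    }
                    for s in scenarios
                ],
            },
        ),
    )
    return out


def run_analyze(manifest_path, out_dir) -> pd.DataFrame:
    """Classify every EEM sample in a manifest; writes shape_report.csv."""
    measurements = load_manifest(manifest_path)
    blanks = {
        m.meta.substrate: m.eem
        for m in measurements
        if m.meta.condition == "blank" and m.eem is not None
    }
    records = []
    for m in measurements:
        if m.eem is None or m.meta.condition == "blank":
            continue
        blank = blanks.get(m.meta.substrate)
        if blank is None and m.meta.condition != "free_ars":
            raise SpecificationError(
                f"missing blank EEM for substrate {m.meta.substrate!r} "
                f"(sample {m.meta.sample_id})"
            )
        eem = subtract_background(m.eem, blank) if blank is not None else m.eem
        report = classify_spectrum(eem)
        records.append(report.to_record(m.meta.sample_id) | {
            "condition": m.meta.condition
        })
    df = pd.DataFrame(records)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "shape_report.csv", index=False)
    return df


def run_calibrate(series_dir, out_dir) -> pd.DataFrame:
    """Fit the three calibrations from a dilution-series directory."""
    series_dir = Path(series_dir)
    measurements = load_manifest(series_dir / "manifest.csv")
    series = series_from_measurements(measurements)
    blank = next(
        (m.od for m in measurements if m.meta.condition == "blank" and m.od is not None),
        None,
    )
    if blank is None:
        raise SpecificationError("dilution series manifest lacks a blank OD spectrum")
    fits = {
        "od_515": calibrate_od(series, blank),
        "f670_exc420": calibrate_fluorescence(series),
        "f670_vs_od": cross_calibrate(series, blank),
    }
    df = pd.DataFrame(
        [
            {
                "channel": name,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
            }
            for name, fit in fits.items()
        ]
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "calibration.csv", index=False)
    return df


def run_quantify(manifest_path, out_dir, control: str = "control") -> pd.DataFrame:
    """Four-method quantification of every non-control condition + the control."""
    measurements = load_manifest(manifest_path)
    conditions = sorted(
        {
            m.meta.condition
            for m in measurements
            if m.meta.condition not in ("blank", "free_ars")
        }
    )
    if control not in conditions:
        raise SpecificationError(f"control condition {control!r} absent from manifest")
    quant_rows, comp_rows = [], []
    for condition in conditions:
        results, comparison = quantify_condition(measurements, condition, control)
        for r in results:
            quant_rows.append(
                {
                    "sample_id": r.sample_id,
                    "condition": r.condition,
                    "method": r.method,
                    "raw_value": r.raw_value,
                    "fold_induction": r.fold_induction,
                    "flags": "",
                }
            )
        for method in comparison.excluded:
            quant_rows.append(
                {
                    "sample_id": f"{condition}:{method}",
                    "condition": condition,
                    "method": method,
                    "raw_value": "",
                    "fold_induction": "",
                    "flags": "excluded_opaque_substrate",
                }
            )
        comp_rows.append(
            {
                "condition": condition,
                "methods": ";".join(sorted(comparison.per_method)),
                "max_pairwise_rel_diff": comparison.max_pairwise_rel_diff,
                "excluded": ";".join(comparison.excluded),
            }
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    quant_df = pd.DataFrame(quant_rows)
    quant_df.to_csv(out / "quantification.csv", index=False)
    pd.DataFrame(comp_rows).to_csv(out / "comparison.csv", index=False)
    return quant_df


def run_report(run_dir) -> pd.DataFrame:
    """Aggregate whatever reports exist under a run directory into summary.csv."""
    run_dir = Path(run_dir)
    frames = []
    for name in ("shape_report.csv", "calibration.csv", "quantification.csv",
                 "comparison.csv"):
        path = run_dir / name
        if path.exists():
            df = pd.read_csv(path)
            df.insert(0, "report", name.removesuffix(".csv"))
            frames.append(df)
    if not frames:
        raise SpecificationError(f"no report CSVs found under {run_dir}")
    summary = pd.concat(frames, ignore_index=True)
    summary.to_csv(run_dir / "summary.csv", index=False)
    return summary
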
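"""Mineralization quantification: ratio index, fold induction, method comparison.

The in-situ statistic is the ratio of the fluorescence intensity at the
670 nm emission maximum to the intensity at the 560 nm saddle, both read at
420 nm excitation.  Being a ratio of two intensities of the same surface, it
is invariant under any scalar attenuation of the signal - which is exactly
why it remains usable on opaque substrates (graphene oxide) where absorbance
readings are not.

Four methods are compared per condition: absorbance at 515 nm and the
fluorescence ratio index, each measured in situ ("surface") or on the acid
extract ("liquid").  All raw values are normalized to the undifferentiated
control measured with the same method ("fold induction").
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .eem import EEM, ODSpectrum, SampleMeta, get_intensity, subtract_background
from .errors import DomainError, SpecificationError

METHODS = ("od_surface", "od_liquid", "fluor_surface", "fluor_liquid")

OD_PEAK_NM = 515.0


@dataclass(frozen=True)
class IndexDefinition:
    """Wavelengths defining the normalized ratio index."""

    exc_nm: float = 420.0
    peak_em_nm: float = 670.0
    saddle_em_nm: float = 560.0

    def __post_init__(self) -> None:
        if not (self.peak_em_nm > self.saddle_em_nm > self.exc_nm + 40.0):
            raise DomainError(
                "index wavelengths must satisfy peak > saddle > excitation + 40 nm"
            )


DEFAULT_INDEX = IndexDefinition()


@dataclass(frozen=True)
class IndexResult:
    """Computed ratio index with its ingredients."""

    value: float
    numerator: float
    denominator: float
    definition: IndexDefinition


@dataclass(frozen=True)
class QuantificationResult:
    """One method's readout for one sample/condition."""

    method: str
    raw_value: float
    fold_induction: float
    sample_id: str
    condition: str


@dataclass
class MethodComparison:
    """Per-method fold inductions for one condition and their spread."""

    condition: str
    per_method: Dict[str, float]
    max_pairwise_rel_diff: float
    excluded: Tuple[str, ...] = ()


@dataclass
class Measurement:
    """A sample's metadata together with whichever spectra were acquired."""

    meta: SampleMeta
    eem: Optional[EEM] = None
    od: Optional[ODSpectrum] = None


def ratio_index(
    eem: EEM,
    definition: IndexDefinition = DEFAULT_INDEX,
    epsilon_frac: float = 1e-6,
) -> IndexResult:
    """The normalized 670/560 ratio at 420 nm excitation.

    The denominator is floored at ``epsilon_frac`` times the surface maximum
    so near-dark samples cannot blow the ratio up.
    """
    gmax = eem.global_max()
    if gmax <= 0:
        raise DomainError("EEM is all zero; the ratio index is undefined")
    numerator = get_intensity(eem, definition.exc_nm, definition.peak_em_nm)
    raw_denominator = get_intensity(eem, definition.exc_nm, definition.saddle_em_nm)
    denominator = max(raw_denominator, epsilon_frac * gmax)
    return IndexResult(
        value=numerator / denominator,
        numerator=numerator,
        denominator=denominator,
        definition=definition,
    )


def od_value(od: ODSpectrum, blank: ODSpectrum) -> float:
    """Blank-subtracted absorbance at the 515 nm ARS peak, clipped at zero."""
    return max(od.at(OD_PEAK_NM) - blank.at(OD_PEAK_NM), 0.0)


def fold_induction(sample_value: float, control_value: float) -> float:
    """Sample readout normalized to the control readout of the same method."""
    if control_value <= 0:
        raise DomainError("control value must be positive for fold induction")
    return sample_value / control_value


def compare_methods(per_method: Dict[str, float], condition: str = "") -> MethodComparison:
    """Maximum pairwise relative difference among per-method fold inductions.

    The relative difference of a pair uses the pair mean as denominator,
    making the statistic symmetric in the two methods.
    """
    if len(per_method) < 2:
        raise SpecificationError("method comparison requires at least two methods")
    max_diff = 0.0
    for a, b in combinations(sorted(per_method), 2):
        fa, fb = per_method[a], per_method[b]
        mean = (fa + fb) / 2.0
        diff = 0.0 if mean == 0 else abs(fa - fb) / mean
        max_diff = max(max_diff, diff)
    return MethodComparison(
        condition=condition, per_method=dict(per_method), max_pairwise_rel_diff=max_diff
    )


def _method_of(meta: SampleMeta, has_eem: bool) -> str:
    return ("fluor_" if has_eem else "od_") + meta.mode


def _blank_lookup(measurements: Sequence[Measurement]):
    """Blanks keyed by (substrate, kind); kind is 'eem' or 'od'."""
    blanks: Dict[Tuple[str, str], object] = {}
    for m in measurements:
        if m.meta.condition != "blank":
            continue
        if m.eem is not None:
            blanks[(m.meta.substrate, "eem")] = m.eem
        if m.od is not None:
            blanks[(m.meta.substrate, "od")] = m.od
    return blanks


def _raw_values(
    measurements: Sequence[Measurement],
    condition: str,
    blanks,
    index_definition: IndexDefinition,
) -> Dict[str, List[float]]:
    """Per-method replicate raw values for one condition, blank-corrected."""
    values: Dict[str, List[float]] = {}
    for m in measurements:
        if m.meta.condition != condition:
            continue
        if m.eem is not None:
            blank = blanks.get((m.meta.substrate, "eem"))
            eem = subtract_background(m.eem, blank) if blank is not None else m.eem
            raw = ratio_index(eem, index_definition).value
            values.setdefault(_method_of(m.meta, True), []).append(raw)
        if m.od is not None:
            blank = blanks.get((m.meta.substrate, "od"))
            if blank is None:
                raise SpecificationError(
                    f"no OD blank for substrate {m.meta.substrate!r}"
                )
            values.setdefault(_method_of(m.meta, False), []).append(
                od_value(m.od, blank)
            )
    return values


def quantify_four_methods(
    measurements: Sequence[Measurement],
    condition: str,
    control_condition: str = "control",
    index_definition: IndexDefinition = DEFAULT_INDEX,
) -> MethodComparison:
    """Fold inductions of one condition by all four methods, and their spread.

    Replicate raw values are averaged per method before the fold is taken.
    On opaque substrates (graphene oxide) the in-situ absorbance carries no
    usable ARS signal, so ``od_surface`` is excluded from the comparison and
    recorded in ``excluded`` rather than imputed.
    """
    results, comparison = quantify_condition(
        measurements, condition, control_condition, index_definition
    )
    return comparison


def quantify_condition(
    measurements: Sequence[Measurement],
    condition: str,
    control_condition: str = "control",
    index_definition: IndexDefinition = DEFAULT_INDEX,
) -> Tuple[List[QuantificationResult], MethodComparison]:
    """Per-method results and the method comparison for one condition."""
    blanks = _blank_lookup(measurements)
    cond_values = _raw_values(measurements, condition, blanks, index_definition)
    control_values = _raw_values(measurements, control_condition, blanks, index_definition)
    if not cond_values:
        raise SpecificationError(f"no measurements for condition {condition!r}")

    substrates = {
        m.meta.substrate
        for m in measurements
        if m.meta.condition == condition and m.meta.mode == "surface"
    }
    excluded: Tuple[str, ...] = ()
    if "go" in substrates and "od_surface" in cond_values:
        del cond_values["od_surface"]
        excluded = ("od_surface",)

    results: List[QuantificationResult] = []
    folds: Dict[str, float] = {}
    for method, vals in sorted(cond_values.items()):
        if method not in control_values:
            raise SpecificationError(
                f"missing control measurement for method {method!r}"
            )
        raw = float(np.mean(vals))
        control_raw = float(np.mean(control_values[method]))
        fold = fold_induction(raw, control_raw)
        folds[method] = fold
        results.append(
            QuantificationResult(
                method=method,
                raw_value=raw,
                fold_induction=fold,
                sample_id=f"{condition}:{method}",
                condition=condition,
            )
        )
    comparison = compare_methods(folds, condition)
    comparison.excluded = excluded
    return results, comparison
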
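"""Core domain types and I/O for 2D fluorescence (excitation-emission) spectra.

An excitation-emission matrix (EEM) is a fluorescence intensity surface
indexed by excitation wavelength (rows) and emission wavelength (columns).
Only the half-plane ``emission >= excitation + 40 nm`` is physically
measurable on the instrument model used here (the +40 nm offset keeps the
detector away from the Rayleigh scatter line), so every EEM carries a boolean
validity mask.  Values outside the mask are undefined and are never read.

Absorbance (optical density) spectra are one-dimensional and carry no mask.

All coordinates in public interfaces are physical wavelengths in nanometres;
no pixel/index conventions are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    FormatError,
    GridMismatchError,
    ValidationError,
)

#: Offset between excitation and the first usable emission wavelength (nm).
SCATTER_OFFSET_NM = 40.0

CONDITIONS = ("control", "om_7d", "om_14d", "go_7d", "go_om_7d", "free_ars", "blank")
SUBSTRATES = ("glass", "go", "solution")
MODES = ("surface", "liquid")

_EEM_COLUMNS = ("excitation_nm", "emission_nm", "intensity")
_OD_COLUMNS = ("wavelength_nm", "od")


def _check_axis(values: np.ndarray, name: str) -> float:
    """Validate a strictly increasing, uniformly spaced wavelength axis.

    Returns the grid step (0.0 for a single-point axis).
    """
    if values.ndim != 1 or values.size == 0:
        raise ValidationError(f"{name} axis must be a non-empty 1-D sequence")
    diffs = np.diff(values)
    if values.size > 1:
        if np.any(diffs <= 0):
            raise ValidationError(f"{name} wavelengths must be strictly increasing")
        step = float(diffs[0])
        if not np.allclose(diffs, step, rtol=0, atol=1e-6):
            raise ValidationError(
                f"{name} wavelengths are not uniformly spaced (ragged grid)"
            )
        return step
    return 0.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Rectangular wavelength grid for an EEM.

    Attributes
    ----------
    excitation_nm, emission_nm:
        Strictly increasing, uniformly spaced wavelength axes (nm).
    step_nm:
        Common grid spacing (nm); derived from the axes.
    """

    excitation_nm: np.ndarray
    emission_nm: np.ndarray
    step_nm: float = field(default=0.0)

    def __post_init__(self) -> None:
        exc = np.asarray(self.excitation_nm, dtype=float)
        em = np.asarray(self.emission_nm, dtype=float)
        object.__setattr__(self, "excitation_nm", exc)
        object.__setattr__(self, "emission_nm", em)
        step_x = _check_axis(exc, "excitation")
        step_m = _check_axis(em, "emission")
        steps = {s for s in (step_x, step_m) if s > 0}
        if len(steps) > 1:
            raise ValidationError(
                f"excitation and emission grid steps differ: {step_x} vs {step_m}"
            )
        object.__setattr__(self, "step_nm", steps.pop() if steps else 0.0)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """Instrument default: excitation 400-580 nm, emission 440-700 nm, 10 nm step."""
        return cls(np.arange(400.0, 581.0, 10.0), np.arange(440.0, 701.0, 10.0))

    @property
    def n_excitation(self) -> int:
        return int(self.excitation_nm.size)

    @property
    def n_emission(self) -> int:
        return int(self.emission_nm.size)

    def scatter_mask(self) -> np.ndarray:
        """Boolean validity mask: True where emission >= excitation + 40 nm."""
        return (
            self.emission_nm[None, :]
            >= self.excitation_nm[:, None] + SCATTER_OFFSET_NM - 1e-9
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.excitation_nm, other.excitation_nm) and np.array_equal(
            self.emission_nm, other.emission_nm
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays
        return hash((self.excitation_nm.tobytes(), self.emission_nm.tobytes()))


@dataclass(frozen=True)
class SampleMeta:
    """Identity and provenance of one measured sample."""

    sample_id: str
    condition: str = "control"
    substrate: str = "glass"
    mode: str = "surface"
    replicate: int = 1
    concentration_mM: Optional[float] = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.substrate not in SUBSTRATES:
            raise ValidationError(f"unknown substrate {self.substrate!r}")
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.replicate < 1:
            raise ValidationError("replicate must be >= 1")
        if self.condition == "free_ars" and self.concentration_mM is None:
            raise ValidationError("free_ars samples require concentration_mM")
        if self.condition == "blank" and self.concentration_mM is not None:
            raise ValidationError("blank samples must not carry a concentration")
        if self.concentration_mM is not None and self.concentration_mM < 0:
            raise ValidationError("concentration_mM must be non-negative")


@dataclass
class EEM:
    """Excitation-emission matrix with a triangular validity mask.

    ``intensity[i, j]`` is the fluorescence count (arbitrary units) at
    excitation ``grid.excitation_nm[i]`` and emission ``grid.emission_nm[j]``.
    Cells where ``mask`` is False are undefined and never read.
    """

    grid: WavelengthGrid
    intensity: np.ndarray
    mask: np.ndarray
    meta: SampleMeta

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = (self.grid.n_excitation, self.grid.n_emission)
        if self.intensity.shape != shape or self.mask.shape != shape:
            raise ValidationError(
                f"intensity/mask shape {self.intensity.shape} does not match grid {shape}"
            )
        scatter = self.grid.scatter_mask()
        if np.any(self.mask & ~scatter):
            raise ValidationError(
                "mask marks cells inside the scatter region (emission < excitation + 40 nm)"
            )
        vals = self.intensity[self.mask]
        if vals.size and np.any(~np.isfinite(vals)):
            raise ValidationError("non-finite intensity on valid cells")
        if vals.size and np.any(vals < -1e-12):
            raise ValidationError("negative intensity on valid cells")

    @classmethod
    def from_intensity(
        cls, grid: WavelengthGrid, intensity: np.ndarray, meta: SampleMeta
    ) -> "EEM":
        """Build an EEM with the full scatter mask; masked cells are zeroed."""
        mask = grid.scatter_mask()
        inten = np.where(mask, np.asarray(intensity, dtype=float), 0.0)
        return cls(grid=grid, intensity=inten, mask=mask, meta=meta)

    def valid_values(self) -> np.ndarray:
        return self.intensity[self.mask]

    def global_max(self) -> float:
        vals = self.valid_values()
        if vals.size == 0:
            raise DomainError("EEM has no valid cells")
        return float(vals.max())

    def with_intensity(self, intensity: np.ndarray, meta: SampleMeta | None = None) -> "EEM":
        return EEM(
            grid=self.grid,
            intensity=np.where(self.mask, intensity, 0.0),
            mask=self.mask.copy(),
            meta=meta if meta is not None else self.meta,
        )

    def copy(self) -> "EEM":
        return EEM(self.grid, self.intensity.copy(), self.mask.copy(), self.meta)


@dataclass
class ODSpectrum:
    """One-dimensional absorbance spectrum (dimensionless OD units)."""

    wavelength_nm: np.ndarray
    od: np.ndarray
    meta: SampleMeta

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.wavelength_nm.shape != self.od.shape or self.wavelength_nm.ndim != 1:
            raise ValidationError("wavelength and od must be 1-D and the same length")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValidationError("OD wavelengths must be strictly increasing")
        if np.any(self.od < -1e-12):
            raise ValidationError("negative OD values")

    def at(self, wavelength_nm: float) -> float:
        """Linear interpolation of the OD at a wavelength inside the covered range."""
        w = self.wavelength_nm
        if not (w[0] - 1e-9 <= wavelength_nm <= w[-1] + 1e-9):
            raise DomainError(
                f"wavelength {wavelength_nm} nm outside covered range [{w[0]}, {w[-1]}]"
            )
        return float(np.interp(wavelength_nm, w, self.od))


@dataclass
class DilutionSeries:
    """Free-dye dilution ladder: matched (EEM, ODSpectrum) pairs per concentration."""

    concentrations_mM: np.ndarray
    samples: list  # list of (EEM, ODSpectrum) tuples, one per concentration

    def __post_init__(self) -> None:
        self.concentrations_mM = np.asarray(self.concentrations_mM, dtype=float)
        if np.any(self.concentrations_mM <= 0):
            raise ValidationError("dilution concentrations must be positive")
        if np.any(np.diff(self.concentrations_mM) <= 0):
            raise ValidationError("dilution concentrations must be strictly increasing")
        if len(self.samples) != self.concentrations_mM.size:
            raise ValidationError("one (EEM, OD) pair required per concentration")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_eem_csv(path, meta: SampleMeta) -> EEM:
    """Read a long-format EEM CSV (columns excitation_nm, emission_nm, intensity).

    The wavelength grid is inferred from the distinct wavelengths present.
    Cells of the scatter half-plane absent from the file are marked invalid.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse EEM CSV {path}: {exc}") from exc
    missing = [c for c in _EEM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    dup = df.duplicated(subset=["excitation_nm", "emission_nm"])
    if dup.any():
        row = int(dup.idxmax()) + 2  # +1 header, +1 one-based
        raise FormatError(f"{path}: duplicate (excitation, emission) pair at row {row}")
    if df["intensity"].isna().any() or not np.all(np.isfinite(df["intensity"])):
        raise ValidationError(f"{path}: non-numeric or missing intensity value")
    if (df["intensity"] < 0).any():
        raise ValidationError(f"{path}: negative intensity value")
    bad = df["emission_nm"] < df["excitation_nm"] + SCATTER_OFFSET_NM - 1e-9
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise ValidationError(
            f"{path}: row {row} lies inside the scatter region "
            "(emission < excitation + 40 nm)"
        )
    exc_vals = np.unique(df["excitation_nm"].to_numpy(dtype=float))
    em_vals = np.unique(df["emission_nm"].to_numpy(dtype=float))
    grid = WavelengthGrid(exc_vals, em_vals)

    inten = np.zeros((grid.n_excitation, grid.n_emission))
    present = np.zeros_like(inten, dtype=bool)
    i_idx = np.searchsorted(exc_vals, df["excitation_nm"].to_numpy(dtype=float))
    j_idx = np.searchsorted(em_vals, df["emission_nm"].to_numpy(dtype=float))
    inten[i_idx, j_idx] = df["intensity"].to_numpy(dtype=float)
    present[i_idx, j_idx] = True
    mask = present & grid.scatter_mask()
    return EEM(grid=grid, intensity=np.where(mask, inten, 0.0), mask=mask, meta=meta)


def write_eem_csv(eem: EEM, path) -> None:
    """Write an EEM as long-format CSV, one row per valid cell.

    Rows are sorted by excitation then emission; floats are written at full
    round-trip precision so write -> read is the identity on valid cells.
    """
    ii, jj = np.nonzero(eem.mask)
    df = pd.DataFrame(
        {
            "excitation_nm": eem.grid.excitation_nm[ii],
            "emission_nm": eem.grid.emission_nm[jj],
            "intensity": eem.intensity[ii, jj],
        }
    ).sort_values(["excitation_nm", "emission_nm"], kind="mergesort")
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc


def write_eem_wide_csv(eem: EEM, path) -> None:
    """Wide export for plotting: emission along columns, blanks for masked cells."""
    data = {"excitation_nm": eem.grid.excitation_nm}
    for j, em in enumerate(eem.grid.emission_nm):
        col = [
            eem.intensity[i, j] if eem.mask[i, j] else None
            for i in range(eem.grid.n_excitation)
        ]
        data[f"{em:g}"] = col
    pd.DataFrame(data).to_csv(path, index=False)


def read_od_csv(path, meta: SampleMeta) -> ODSpectrum:
    """Read an OD CSV (columns wavelength_nm, od)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse OD CSV {path}: {exc}") from exc
    missing = [c for c in _OD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return ODSpectrum(
        wavelength_nm=df["wavelength_nm"].to_numpy(dtype=float),
        od=df["od"].to_numpy(dtype=float),
        meta=meta,
    )


def write_od_csv(od: ODSpectrum, path) -> None:
    pd.DataFrame({"wavelength_nm": od.wavelength_nm, "od": od.od}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def subtract_background(sample: EEM, blank: EEM) -> EEM:
    """Cellwise blank subtraction, clipped at zero.

    Fluorescence counts are non-negative, and downstream ratio statistics
    must never divide by a negative value, so differences are clipped.
    """
    if sample.grid != blank.grid or not np.array_equal(sample.mask, blank.mask):
        raise GridMismatchError("sample and blank EEMs must share grid and mask")
    diff = np.clip(sample.intensity - blank.intensity, 0.0, None)
    return sample.with_intensity(diff)


def get_intensity(eem: EEM, exc_nm: float, em_nm: float) -> float:
    """Intensity at a wavelength pair; bilinear interpolation off-grid.

    Exact cell value when both wavelengths are on-grid.  Every cell with a
    non-zero interpolation weight must be valid, otherwise the query is
    outside the measurable region and a :class:`DomainError` is raised.
    """
    ex, em = eem.grid.excitation_nm, eem.grid.emission_nm
    if not (ex[0] - 1e-9 <= exc_nm <= ex[-1] + 1e-9):
        raise DomainError(f"excitation {exc_nm} nm outside grid [{ex[0]}, {ex[-1]}]")
    if not (em[0] - 1e-9 <= em_nm <= em[-1] + 1e-9):
        raise DomainError(f"emission {em_nm} nm outside grid [{em[0]}, {em[-1]}]")

    def bracket(axis: np.ndarray, x: float) -> tuple[int, int, float]:
        i = int(np.searchsorted(axis, x, side="right")) - 1
        i = min(max(i, 0), axis.size - 1)
        if abs(axis[i] - x) < 1e-9:
            return i, i, 0.0
        if i == axis.size - 1:
            i -= 1
        t = (x - axis[i]) / (axis[i + 1] - axis[i])
        return i, i + 1, float(t)

    i0, i1, tx = bracket(ex, float(exc_nm))
    j0, j1, ty = bracket(em, float(em_nm))
    total = 0.0
    for i, wi in ((i0, 1.0 - tx), (i1, tx)):
        for j, wj in ((j0, 1.0 - ty), (j1, ty)):
            w = wi * wj
            if w <= 1e-12:
                continue
            if not eem.mask[i, j]:
                raise DomainError(
                    f"query ({exc_nm}, {em_nm}) nm touches an invalid (masked) cell"
                )
            total += w * eem.intensity[i, j]
    return float(total)
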
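"""Shape analysis of EEM surfaces.

The fluorescence surface of a mineralizing culture changes shape as the
ARS-calcium complex forms: the single cellular emission peak near 500 nm is
joined by a complex peak at 670 nm, and a saddle appears between them near
560 nm emission.  This module detects and classifies stationary points of a
smoothed EEM surface and turns them into a shape fingerprint.

Stationary cells are found by a central-difference gradient test and
classified by the eigenvalue signs of the discrete Hessian.  Because a
tolerance-based gradient test inevitably admits cells on gentle slopes and
plateaus, every candidate must additionally be corroborated by the discrete
neighbourhood pattern on the same smoothed surface: a maximum must strictly
dominate its 8 neighbours, a minimum must be strictly dominated, and a
saddle must be a strict extremum of opposite sense along the two grid axes.
This "double evidence" rule makes the detector exactly equivalent to an
exhaustive neighbour-comparison scan on well-resolved surfaces and immune to
spurious classifications on noisy plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal

from .eem import EEM
from .errors import DomainError, ParameterError, GridMismatchError

KINDS = ("maximum", "minimum", "saddle")

#: Default smoothing bandwidth in grid units (1.0 = one 10 nm step).
DEFAULT_SIGMA = 1.0
#: Default stationarity tolerance as a fraction of the surface dynamic range.
DEFAULT_GRAD_TOL_FRAC = 0.02
#: Minimum relief (fraction of dynamic range) for a 1-D emission minimum or
#: peak to count as a real spectral feature rather than plateau noise.  Set
#: above the residual cell-to-cell variation that survives smoothing at the
#: instrument's ~1-2% noise level; the mineralization saddle's relief is an
#: order of magnitude larger.
DEFAULT_PROMINENCE_FRAC = 0.02
#: Saddle search window on the emission axis (nm) and the excitation slice
#: used for the 1-D signature check.
DEFAULT_EM_WINDOW = (520.0, 600.0)
DEFAULT_EXC_PROBE = 420.0

_HESSIAN_EIG_FLOOR_FRAC = 1e-9


@dataclass(frozen=True)
class CriticalPoint:
    """A classified stationary point of a smoothed EEM surface."""

    exc_nm: float
    em_nm: float
    intensity: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"unknown critical point kind {self.kind!r}")


@dataclass
class ShapeReport:
    """Shape fingerprint of one EEM."""

    critical_points: list
    has_saddle: bool
    saddle: Optional[CriticalPoint]
    primary_peak: Optional[CriticalPoint]
    classification: str

    def to_record(self, sample_id: str = "") -> dict:
        return {
            "sample_id": sample_id,
            "classification": self.classification,
            "has_saddle": self.has_saddle,
            "saddle_exc_nm": self.saddle.exc_nm if self.saddle else None,
            "saddle_em_nm": self.saddle.em_nm if self.saddle else None,
            "peak_exc_nm": self.primary_peak.exc_nm if self.primary_peak else None,
            "peak_em_nm": self.primary_peak.em_nm if self.primary_peak else None,
        }


def smooth_eem(eem: EEM, sigma_grid_units: float = DEFAULT_SIGMA) -> EEM:
    """Mask-aware Gaussian smoothing.

    The kernel is renormalized over valid cells only, so constants are
    preserved up to the mask boundary and no information bleeds across the
    scatter mask.  ``sigma_grid_units = 0`` returns the input unchanged.
    """
    if sigma_grid_units < 0:
        raise ParameterError("smoothing sigma must be non-negative")
    if sigma_grid_units == 0:
        return eem.copy()
    weights = eem.mask.astype(float)
    num = ndimage.gaussian_filter(
        np.where(eem.mask, eem.intensity, 0.0), sigma_grid_units, mode="constant"
    )
    den = ndimage.gaussian_filter(weights, sigma_grid_units, mode="constant")
    smoothed = np.where(eem.mask, num / np.maximum(den, 1e-300), 0.0)
    return eem.with_intensity(smoothed)


def _interior_mask(mask: np.ndarray) -> np.ndarray:
    """Valid cells whose full 3x3 neighbourhood is valid (never mask-boundary)."""
    return ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)


def _neighbour_kind(s: np.ndarray, i: int, j: int, tie_eps: float = 0.0) -> Optional[str]:
    """Discrete neighbourhood classification of interior cell (i, j).

    maximum/minimum: strict 8-neighbour comparison; saddle: strict maximum
    along one grid axis and strict minimum along the other.  Differences of
    magnitude <= ``tie_eps`` count as ties (guards plateaus against
    floating-point wiggle).
    """
    c = s[i, j]
    block = s[i - 1 : i + 2, j - 1 : j + 2]
    others = np.delete(block.ravel(), 4)
    if np.all(c > others + tie_eps):
        return "maximum"
    if np.all(c < others - tie_eps):
        return "minimum"
    axis_exc_max = c > s[i - 1, j] + tie_eps and c > s[i + 1, j] + tie_eps
    axis_exc_min = c < s[i - 1, j] - tie_eps and c < s[i + 1, j] - tie_eps
    axis_em_max = c > s[i, j - 1] + tie_eps and c > s[i, j + 1] + tie_eps
    axis_em_min = c < s[i, j - 1] - tie_eps and c < s[i, j + 1] - tie_eps
    if (axis_exc_max and axis_em_min) or (axis_exc_min and axis_em_max):
        return "saddle"
    return None


def find_critical_points(
    eem: EEM,
    sigma_grid_units: float = DEFAULT_SIGMA,
    grad_tol_frac: float = DEFAULT_GRAD_TOL_FRAC,
) -> list:
    """Detect and classify stationary points of the smoothed surface.

    A valid interior cell is stationary when both central-difference gradient
    components (per grid step) are below ``grad_tol_frac`` times the surface
    dynamic range.  Stationary cells are classified by the sign pattern of
    the discrete Hessian eigenvalues and must be corroborated by the strict
    neighbourhood pattern (see module docstring).  Adjacent stationary cells
    of the same kind are merged to the one with extremal intensity.
    """
    if not (0 < grad_tol_frac <= 0.1):
        raise ParameterError("grad_tol_frac must lie in (0, 0.1]")
    smoothed = smooth_eem(eem, sigma_grid_units)
    s = smoothed.intensity
    interior = _interior_mask(smoothed.mask)
    # the 3x3 stencils below additionally need array-interior cells
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    if int(interior.sum()) < 25:
        raise DomainError("EEM too small: need at least 5x5 valid interior cells")

    vals = s[smoothed.mask]
    dyn_range = float(vals.max() - vals.min())
    if dyn_range <= 0:
        return []  # degenerate (constant) surface

    gx = np.zeros_like(s)
    gy = np.zeros_like(s)
    gx[1:-1, :] = (s[2:, :] - s[:-2, :]) / 2.0
    gy[:, 1:-1] = (s[:, 2:] - s[:, :-2]) / 2.0
    # A cell is stationary along an axis when the central-difference gradient
    # (per grid step) is below tolerance, or when the one-sided differences
    # change sign, i.e. the cell brackets a discrete extremum.  The second
    # branch keeps sharp on-node peaks whose central difference is inflated
    # by kernel renormalization near the scatter-mask staircase.
    fwd_x = np.full_like(s, np.nan)
    bwd_x = np.full_like(s, np.nan)
    fwd_y = np.full_like(s, np.nan)
    bwd_y = np.full_like(s, np.nan)
    fwd_x[:-1, :] = s[1:, :] - s[:-1, :]
    bwd_x[1:, :] = s[1:, :] - s[:-1, :]
    fwd_y[:, :-1] = s[:, 1:] - s[:, :-1]
    bwd_y[:, 1:] = s[:, 1:] - s[:, :-1]
    tol = grad_tol_frac * dyn_range
    with np.errstate(invalid="ignore"):
        stat_x = (np.abs(gx) < tol) | (fwd_x * bwd_x < 0)
        stat_y = (np.abs(gy) < tol) | (fwd_y * bwd_y < 0)
    stationary = interior & stat_x & stat_y

    fxx = np.zeros_like(s)
    fyy = np.zeros_like(s)
    fxy = np.zeros_like(s)
    fxx[1:-1, :] = s[2:, :] - 2 * s[1:-1, :] + s[:-2, :]
    fyy[:, 1:-1] = s[:, 2:] - 2 * s[:, 1:-1] + s[:, :-2]
    fxy[1:-1, 1:-1] = (
        s[2:, 2:] - s[2:, :-2] - s[:-2, 2:] + s[:-2, :-2]
    ) / 4.0

    mean = (fxx + fyy) / 2.0
    disc = np.sqrt(((fxx - fyy) / 2.0) ** 2 + fxy**2)
    lam1, lam2 = mean - disc, mean + disc
    eig_floor = _HESSIAN_EIG_FLOOR_FRAC * dyn_range

    kind_grid = np.full(s.shape, "", dtype=object)
    for i, j in zip(*np.nonzero(stationary)):
        l1, l2 = lam1[i, j], lam2[i, j]
        if abs(l1) < eig_floor or abs(l2) < eig_floor:
            continue  # indeterminate curvature
        if l1 < 0 and l2 < 0:
            kind = "maximum"
        elif l1 > 0 and l2 > 0:
            kind = "minimum"
        else:
            kind = "saddle"
        if _neighbour_kind(s, i, j, tie_eps=eig_floor) == kind:
            kind_grid[i, j] = kind

    points: list[CriticalPoint] = []
    eight = np.ones((3, 3), bool)
    for kind in KINDS:
        labels, n_comp = ndimage.label(kind_grid == kind, structure=eight)
        for comp in range(1, n_comp + 1):
            cells = list(zip(*np.nonzero(labels == comp)))
            if kind == "minimum":
                best = min(cells, key=lambda ij: (s[ij], eem.grid.emission_nm[ij[1]]))
            else:
                # maxima and saddles keep the most intense cell; ties break
                # to the lowest emission wavelength
                best = max(cells, key=lambda ij: (s[ij], -eem.grid.emission_nm[ij[1]]))
            i, j = best
            points.append(
                CriticalPoint(
                    exc_nm=float(eem.grid.excitation_nm[i]),
                    em_nm=float(eem.grid.emission_nm[j]),
                    intensity=float(s[i, j]),
                    kind=kind,
                )
            )
    points.sort(key=lambda p: (KINDS.index(p.kind), p.exc_nm, p.em_nm))
    return points


def _emission_profile(smoothed: EEM, exc_nm: float) -> tuple[np.ndarray, np.ndarray]:
    """Valid (emission, intensity) slice of a smoothed EEM at one excitation row."""
    idx = np.where(np.abs(smoothed.grid.excitation_nm - exc_nm) < 1e-9)[0]
    if idx.size == 0:
        raise DomainError(f"excitation {exc_nm} nm is not on the grid")
    i = int(idx[0])
    valid = smoothed.mask[i]
    return smoothed.grid.emission_nm[valid], smoothed.intensity[i, valid]


def _profile_minima(
    em: np.ndarray, profile: np.ndarray, prominence: float
) -> np.ndarray:
    idx, _ = signal.find_peaks(-profile, prominence=prominence)
    return em[idx]


def _profile_maxima(
    em: np.ndarray, profile: np.ndarray, prominence: float
) -> np.ndarray:
    idx, _ = signal.find_peaks(profile, prominence=prominence)
    return em[idx]


def _saddle_evidence(
    eem: EEM,
    em_window_nm: tuple[float, float],
    exc_probe_nm: float,
    sigma_grid_units: float,
    grad_tol_frac: float,
    prominence_frac: float,
) -> tuple[Optional[CriticalPoint], bool]:
    """Two independent saddle checks: 2-D stationary point and 1-D slice signature.

    Returns ``(best 2-D saddle in the emission window or None, whether the
    emission profile at the probe excitation has a prominent local minimum in
    the window)``.
    """
    smoothed = smooth_eem(eem, sigma_grid_units)
    vals = smoothed.valid_values()
    dyn_range = float(vals.max() - vals.min())
    if dyn_range <= 0:
        return None, False
    prominence = prominence_frac * dyn_range

    # The surface is nearly flat along excitation around the saddle, so the
    # discrete 2-D detection is run at two smoothing scales; a saddle found
    # at either scale counts.  Each scale uses its own smoothed surface for
    # the row-prominence significance check.
    best = None
    for sigma in (sigma_grid_units, 1.5 * sigma_grid_units if sigma_grid_units > 0 else 1.0):
        scale_smoothed = smoothed if sigma == sigma_grid_units else smooth_eem(eem, sigma)
        candidates = []
        for p in find_critical_points(eem, sigma, grad_tol_frac):
            if p.kind != "saddle" or not (em_window_nm[0] <= p.em_nm <= em_window_nm[1]):
                continue
            # significance: the saddle must be a prominent minimum of the
            # emission slice at its own excitation, not a plateau artefact
            em_row, profile_row = _emission_profile(scale_smoothed, p.exc_nm)
            minima = _profile_minima(em_row, profile_row, prominence)
            if np.any(np.abs(minima - p.em_nm) <= eem.grid.step_nm + 1e-9):
                candidates.append(p)
        if candidates:
            best = max(candidates, key=lambda p: (p.intensity, -p.em_nm))
            break

    em_probe, profile_probe = _emission_profile(smoothed, exc_probe_nm)
    minima = _profile_minima(em_probe, profile_probe, prominence)
    in_window = minima[(minima >= em_window_nm[0]) & (minima <= em_window_nm[1])]
    return best, bool(in_window.size)


def detect_saddle(
    eem: EEM,
    em_window_nm: tuple[float, float] = DEFAULT_EM_WINDOW,
    exc_probe_nm: float = DEFAULT_EXC_PROBE,
    sigma_grid_units: float = DEFAULT_SIGMA,
    grad_tol_frac: float = DEFAULT_GRAD_TOL_FRAC,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> Optional[CriticalPoint]:
    """The mineralization saddle, or None when absent.

    Both the 2-D stationary-point check and the 1-D emission-slice signature
    at the probe excitation must agree for a saddle to be reported; absence
    is a valid result, not an error.
    """
    saddle, has_1d = _saddle_evidence(
        eem, em_window_nm, exc_probe_nm, sigma_grid_units, grad_tol_frac, prominence_frac
    )
    return saddle if (saddle is not None and has_1d) else None


def classify_spectrum(
    eem: EEM,
    sigma_grid_units: float = DEFAULT_SIGMA,
    grad_tol_frac: float = DEFAULT_GRAD_TOL_FRAC,
    em_window_nm: tuple[float, float] = DEFAULT_EM_WINDOW,
    exc_probe_nm: float = DEFAULT_EXC_PROBE,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> ShapeReport:
    """Classify an EEM by its shape fingerprint.

    ``mineralized_double_peak``: both saddle checks agree - a prominent
    emission minimum necessarily sits between two higher emission lobes, so
    agreement certifies the double-peaked profile even when the red lobe is
    truncated at the detector's 700 nm edge.  ``undifferentiated_single_peak``:
    single prominent maximum below 560 nm.  ``free_dye_single_peak``: single
    maximum above 600 nm.  Anything else (including disagreement between the
    two saddle checks) is ``indeterminate``.
    """
    smoothed = smooth_eem(eem, sigma_grid_units)
    vals = smoothed.valid_values()
    dyn_range = float(vals.max() - vals.min())

    critical_points = (
        find_critical_points(eem, sigma_grid_units, grad_tol_frac) if dyn_range > 0 else []
    )

    primary_peak = None
    if dyn_range > 0:
        flat = np.where(smoothed.mask, smoothed.intensity, -np.inf)
        i, j = np.unravel_index(int(np.argmax(flat)), flat.shape)
        primary_peak = CriticalPoint(
            exc_nm=float(smoothed.grid.excitation_nm[i]),
            em_nm=float(smoothed.grid.emission_nm[j]),
            intensity=float(smoothed.intensity[i, j]),
            kind="maximum",
        )

    if dyn_range <= 0:
        return ShapeReport([], False, None, None, "indeterminate")

    saddle, has_1d = _saddle_evidence(
        eem, em_window_nm, exc_probe_nm, sigma_grid_units, grad_tol_frac, prominence_frac
    )
    em_probe, profile_probe = _emission_profile(smoothed, exc_probe_nm)
    peaks = _profile_maxima(em_probe, profile_probe, prominence_frac * dyn_range)

    if saddle is not None and has_1d:
        return ShapeReport(critical_points, True, saddle, primary_peak,
                           "mineralized_double_peak")
    if (saddle is not None) != has_1d:
        return ShapeReport(critical_points, False, None, primary_peak, "indeterminate")
    if peaks.size == 1 and peaks[0] < 560.0:
        return ShapeReport(critical_points, False, None, primary_peak,
                           "undifferentiated_single_peak")
    if peaks.size == 1 and peaks[0] > 600.0:
        return ShapeReport(critical_points, False, None, primary_peak,
                           "free_dye_single_peak")
    return ShapeReport(critical_points, False, None, primary_peak, "indeterminate")


def shape_invariance_score(reference: EEM, others: Sequence[EEM]) -> float:
    """How far a family of EEMs departs from rigid scaling of a reference.

    Each EEM is normalized to unit maximum over valid cells; the score is the
    largest absolute difference between any normalized member and the
    normalized reference, over all valid cells.  0 means perfectly rigid
    intensity scaling (identical shapes); the score is bounded by 1.
    """
    ref_max = reference.global_max()
    if ref_max <= 0:
        raise DomainError("reference EEM is all zero; cannot normalize")
    ref_norm = reference.intensity / ref_max
    score = 0.0
    for other in others:
        if other.grid != reference.grid or not np.array_equal(other.mask, reference.mask):
            raise GridMismatchError("all EEMs must share grid and mask")
        other_max = other.global_max()
        if other_max <= 0:
            raise DomainError("EEM is all zero; cannot normalize")
        diff = np.abs(other.intensity / other_max - ref_norm)[reference.mask]
        score = max(score, float(diff.max()))
    return score
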
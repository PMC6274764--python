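"""Linear concentration-signal calibrations.

Free Alizarin Red S in solution obeys Beer-Lambert absorbance at 515 nm and
a linear fluorescence response at 670 nm (420 nm excitation) over the
working range, so both channels calibrate with ordinary least squares.  The
cross-calibration (fluorescence against absorbance) links the two readouts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .eem import DilutionSeries, ODSpectrum, get_intensity
from .errors import DomainError
from .quantify import OD_PEAK_NM, DEFAULT_INDEX

F670_EXC_NM = DEFAULT_INDEX.exc_nm
F670_EM_NM = DEFAULT_INDEX.peak_em_nm


@dataclass(frozen=True)
class CalibrationFit:
    """Ordinary least-squares line with goodness of fit.

    slope is in signal units per mM (or signal per signal for the
    cross-calibration); r_squared = 1 - SS_res / SS_tot.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    residuals: tuple


def fit_linear(x: Sequence[float], y: Sequence[float]) -> CalibrationFit:
    """OLS with intercept; requires >= 3 points and non-degenerate x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D and the same length")
    if x.size < 3:
        raise DomainError("linear calibration requires at least 3 points")
    if np.ptp(x) == 0:
        raise DomainError("degenerate x: all abscissa values identical")
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    residuals = y - fitted
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r_squared,
        n_points=int(x.size),
        residuals=tuple(float(r) for r in residuals),
    )


def _series_od(series: DilutionSeries, blank: ODSpectrum) -> np.ndarray:
    return np.array(
        [max(od.at(OD_PEAK_NM) - blank.at(OD_PEAK_NM), 0.0) for _, od in series.samples]
    )


def _series_f670(series: DilutionSeries) -> np.ndarray:
    return np.array(
        [get_intensity(eem, F670_EXC_NM, F670_EM_NM) for eem, _ in series.samples]
    )


def calibrate_od(series: DilutionSeries, blank: ODSpectrum) -> CalibrationFit:
    """Blank-subtracted absorbance at 515 nm against concentration (mM)."""
    return fit_linear(series.concentrations_mM, _series_od(series, blank))


def calibrate_fluorescence(series: DilutionSeries) -> CalibrationFit:
    """Fluorescence at (420, 670) nm against concentration (mM)."""
    return fit_linear(series.concentrations_mM, _series_f670(series))


def cross_calibrate(series: DilutionSeries, blank: ODSpectrum) -> CalibrationFit:
    """Fluorescence at (420, 670) nm against blank-subtracted absorbance at 515 nm."""
    return fit_linear(_series_od(series, blank), _series_f670(series))


def predict_concentration(fit: CalibrationFit, signal: float) -> float:
    """Inverse prediction (signal - intercept) / slope; may be negative."""
    if fit.slope == 0:
        raise DomainError("zero slope: cannot invert calibration")
    return (signal - fit.intercept) / fit.slope
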
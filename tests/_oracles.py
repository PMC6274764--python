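"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: the neighbour scan uses
exhaustive strict comparisons instead of gradient/Hessian analysis, the
smoothing oracle is a direct nested-loop convolution, and the least-squares
oracle solves the normal equations from explicit sums.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from arsq.shape import smooth_eem


def neighbour_scan(eem, sigma_grid_units: float = 1.0):
    """Exhaustive 8-neighbour critical-point scan on the smoothed surface.

    maxima/minima: strictly above/below all 8 neighbours; saddles: strict
    extremum of opposite sense along the two grid axes.  Differences below
    1e-9 of the dynamic range count as ties (plateau float noise).
    Returns a set of (exc_nm, em_nm, kind) tuples.
    """
    smoothed = smooth_eem(eem, sigma_grid_units)
    s = smoothed.intensity
    interior = ndimage.binary_erosion(
        smoothed.mask, structure=np.ones((3, 3), bool), border_value=0
    )
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    vals = s[smoothed.mask]
    eps = 1e-9 * float(vals.max() - vals.min())
    found = set()
    for i, j in zip(*np.nonzero(interior)):
        c = s[i, j]
        others = np.delete(s[i - 1 : i + 2, j - 1 : j + 2].ravel(), 4)
        kind = None
        if np.all(c > others + eps):
            kind = "maximum"
        elif np.all(c < others - eps):
            kind = "minimum"
        else:
            xmax = c > s[i - 1, j] + eps and c > s[i + 1, j] + eps
            xmin = c < s[i - 1, j] - eps and c < s[i + 1, j] - eps
            ymax = c > s[i, j - 1] + eps and c > s[i, j + 1] + eps
            ymin = c < s[i, j - 1] - eps and c < s[i, j + 1] - eps
            if (xmax and ymin) or (xmin and ymax):
                kind = "saddle"
        if kind:
            found.add(
                (
                    float(eem.grid.excitation_nm[i]),
                    float(eem.grid.emission_nm[j]),
                    kind,
                )
            )
    return found


def direct_masked_convolution(intensity, mask, sigma, radius=None):
    """Nested-loop mask-renormalized Gaussian smoothing (reference)."""
    n, m = intensity.shape
    if radius is None:
        radius = int(4 * sigma + 0.5)
    offsets = np.arange(-radius, radius + 1)
    kernel = np.exp(-(offsets[:, None] ** 2 + offsets[None, :] ** 2) / (2 * sigma**2))
    out = np.zeros_like(intensity, dtype=float)
    for i in range(n):
        for j in range(m):
            if not mask[i, j]:
                continue
            num = den = 0.0
            for a, di in enumerate(offsets):
                for b, dj in enumerate(offsets):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n and 0 <= jj < m and mask[ii, jj]:
                        num += kernel[a, b] * intensity[ii, jj]
                        den += kernel[a, b]
            out[i, j] = num / den
    return out


def normal_equations_fit(x, y):
    """Closed-form simple linear regression from explicit sums."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2
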
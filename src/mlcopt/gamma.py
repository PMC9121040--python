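"""2D gamma-index comparison of dose planes.

The gamma index of Low et al. combines a dose-difference criterion (%DD,
normalized to a single global dose or to the local reference dose) and a
distance-to-agreement criterion (DTA).  For a reference point r with dose
D_ref and an evaluated distribution D_eval:

    gamma(r) = min over r' of sqrt( |r' - r|^2 / dta^2
                                    + (D_eval(r') - D_ref)^2 / (dd * D_norm)^2 )

A pixel passes when gamma <= 1 (boundary inclusive).  Summary statistics are
computed over reference pixels at or above a low-dose threshold: the pass
rate (fraction of masked pixels with gamma <= 1) and the mean gamma (sum of
gamma over masked pixels divided by the number of masked pixels).

Search strategy: the evaluated plane is upsampled by an integer factor with
separable bilinear interpolation and the minimum is taken over all upsampled
points within ``search_factor * dta`` of each reference pixel.  Reference
pixels near the edge of the evaluated plane use whatever candidates exist;
nothing is padded or extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import DEFAULTS
from .planes import DegenerateInputError, DosePlane, GeometryError, ValidationError

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "resolve_norm_dose",
    "threshold_mask",
    "compute_gamma",
    "summarize",
    "bilinear_upsample",
]


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma analysis criteria.

    dta is in mm; dd and threshold are fractions of the normalization dose
    (0.02 means 2%).  ``normalization`` is "global" (one dose for the whole
    plane) or "local" (each reference pixel's own dose in the %DD term; the
    low-dose threshold is always referenced to the global dose).  If
    ``norm_dose`` is None the global dose is the maximum of the reference
    (measured) plane.
    """

    dta: float = DEFAULTS.dta_mm
    dd: float = DEFAULTS.dd_fraction
    threshold: float = DEFAULTS.threshold_fraction
    normalization: str = DEFAULTS.normalization
    norm_dose: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.dta > 0:
            raise ValidationError(f"dta must be > 0, got {self.dta}")
        if not self.dd > 0:
            raise ValidationError(f"dd must be > 0, got {self.dd}")
        if not 0 <= self.threshold < 1:
            raise ValidationError(
                f"threshold must be in [0, 1), got {self.threshold}"
            )
        if self.normalization not in ("global", "local"):
            raise ValidationError(
                f"normalization must be 'global' or 'local', got "
                f"{self.normalization!r}"
            )
        if self.norm_dose is not None and not self.norm_dose > 0:
            raise ValidationError(f"norm_dose must be > 0, got {self.norm_dose}")


@dataclass
class GammaResult:
    """Gamma map plus summary statistics.

    ``gamma_map`` is NaN below the dose threshold; ``mask`` marks
    above-threshold reference pixels.
    """

    gamma_map: np.ndarray
    mask: np.ndarray
    pass_rate: float
    mean_gamma: float
    criteria: GammaCriteria


def resolve_norm_dose(reference: DosePlane, criteria: GammaCriteria) -> float:
    """The global normalization dose: explicit ``norm_dose`` if given, else
    the maximum dose of the reference (measured) plane."""
    if criteria.norm_dose is not None:
        return float(criteria.norm_dose)
    dmax = float(reference.values.max())
    if dmax <= 0:
        raise DegenerateInputError(
            "reference plane is identically zero; normalization dose undefined"
        )
    return dmax


def threshold_mask(reference: DosePlane, criteria: GammaCriteria) -> np.ndarray:
    """Boolean mask of reference pixels at or above threshold x D_norm.

    The threshold is applied to the reference (measured) plane only.
    """
    dnorm = resolve_norm_dose(reference, criteria)
    mask = reference.values >= criteria.threshold * dnorm
    if not mask.any():
        raise DegenerateInputError(
            "no reference pixel is above the dose threshold "
            f"({criteria.threshold:.3g} x {dnorm:.4g} cGy)"
        )
    return mask


def summarize(gamma_map: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """(pass_rate, mean_gamma) over masked pixels; gamma <= 1 passes."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty mask: no pixels to summarize")
    g = np.asarray(gamma_map, dtype=float)[mask]
    if np.any(np.isnan(g)):
        raise ValidationError("gamma undefined on some masked pixels")
    pass_rate = float(np.count_nonzero(g <= 1.0) / g.size)
    mean_gamma = float(g.sum() / g.size)
    return pass_rate, mean_gamma


def bilinear_upsample(values: np.ndarray, factor: int) -> np.ndarray:
    """Separable exact bilinear upsampling on the pixel lattice.

    Output sample k along an axis of length n sits at original index k/factor,
    for k = 0 .. (n-1)*factor; endpoints coincide with the original pixels.
    """
    if factor < 1 or int(factor) != factor:
        raise ValidationError(f"upsample factor must be a positive integer, got {factor}")
    factor = int(factor)
    out = np.asarray(values, dtype=float)
    if factor == 1:
        return out.copy()
    for axis in (0, 1):
        out = np.moveaxis(out, axis, 0)
        n = out.shape[0]
        idx = np.arange((n - 1) * factor + 1)
        lo = idx // factor
        frac = (idx - lo * factor) / factor
        hi = np.minimum(lo + 1, n - 1)
        out = (1.0 - frac)[:, None] * out[lo] + frac[:, None] * out[hi]
        out = np.moveaxis(out, 0, axis)
    return out


def _check_overlap(reference: DosePlane, evaluated: DosePlane) -> None:
    rx0, rx1, ry0, ry1 = reference.extent()
    ex0, ex1, ey0, ey1 = evaluated.extent()
    if rx1 < ex0 or ex1 < rx0 or ry1 < ey0 or ey1 < ry0:
        raise GeometryError(
            "reference and evaluated planes do not overlap: "
            f"reference x[{rx0},{rx1}] y[{ry0},{ry1}] vs "
            f"evaluated x[{ex0},{ex1}] y[{ey0},{ey1}] (mm)"
        )


def compute_gamma(
    reference: DosePlane,
    evaluated: DosePlane,
    criteria: GammaCriteria = GammaCriteria(),
    search_factor: float = DEFAULTS.search_factor,
    upsample_factor: int = DEFAULTS.upsample_factor,
) -> GammaResult:
    """Gamma of ``evaluated`` against ``reference`` at every above-threshold
    reference pixel.

    The evaluated plane is kept on its native grid and sampled through
    bilinear upsampling; the reference plane is never resampled.
    """
    if not search_factor > 0:
        raise ValidationError(f"search_factor must be > 0, got {search_factor}")
    if np.any(~np.isfinite(reference.values)) or np.any(~np.isfinite(evaluated.values)):
        raise ValidationError("NaN or infinite dose in input plane")
    _check_overlap(reference, evaluated)

    dnorm = resolve_norm_dose(reference, criteria)
    mask = threshold_mask(reference, criteria)

    fine = bilinear_upsample(evaluated.values, upsample_factor)
    step_x = evaluated.spacing_x / upsample_factor
    step_y = evaluated.spacing_y / upsample_factor
    fx = evaluated.origin_x + step_x * np.arange(fine.shape[1])
    # row 0 is the top row: y descends with row index
    fy = evaluated.origin_y - step_y * np.arange(fine.shape[0])

    radius = search_factor * criteria.dta
    rows, cols = np.nonzero(mask)
    xr = reference.origin_x + reference.spacing_x * cols
    yr = reference.origin_y - reference.spacing_y * rows
    dref = reference.values[rows, cols]

    if criteria.normalization == "local":
        beta = criteria.dd * dref
    else:
        beta = np.full(dref.shape, criteria.dd * dnorm)

    gamma_vals = _min_gamma(
        fine, fx, fy, step_x, step_y, xr, yr, dref, beta, radius, criteria.dta
    )

    gamma_map = np.full(reference.values.shape, np.nan)
    gamma_map[rows, cols] = gamma_vals
    pass_rate, mean_gamma = summarize(gamma_map, mask)
    return GammaResult(gamma_map, mask, pass_rate, mean_gamma, criteria)


def _gamma_sq(dist_sq, dose_eval, dref, beta, dta):
    """gamma^2 terms; a zero local normalization with exact dose agreement
    contributes no dose penalty."""
    diff = dose_eval - dref
    with np.errstate(divide="ignore", invalid="ignore"):
        dose_term = (diff / beta) ** 2
    dose_term = np.where(diff == 0.0, 0.0, dose_term)
    return dist_sq / dta**2 + dose_term


def _min_gamma(fine, fx, fy, step_x, step_y, xr, yr, dref, beta, radius, dta):
    """Radius-limited minimum gamma for each reference point.

    Points whose positions coincide with the upsampled lattice and whose
    search disc is interior to the evaluated plane are handled in one
    vectorized gather; the remainder fall back to a per-point window search.
    """
    n = xr.size
    out = np.empty(n)
    ny, nx = fine.shape
    neg_fy = -fy  # ascending, for searchsorted

    # continuous fine-lattice coordinates of each reference point
    cjf = (xr - fx[0]) / step_x
    cif = (fy[0] - yr) / step_y
    cj = np.rint(cjf).astype(int)
    ci = np.rint(cif).astype(int)
    rx = int(np.floor(radius / step_x))
    ry = int(np.floor(radius / step_y))
    aligned = (
        (np.abs(cjf - cj) < 1e-9)
        & (np.abs(cif - ci) < 1e-9)
        & (cj - rx >= 0)
        & (cj + rx < nx)
        & (ci - ry >= 0)
        & (ci + ry < ny)
    )

    if aligned.any():
        di, dj = np.meshgrid(
            np.arange(-ry, ry + 1), np.arange(-rx, rx + 1), indexing="ij"
        )
        dist_sq = (di * step_y) ** 2 + (dj * step_x) ** 2
        keep = dist_sq <= radius**2 + 1e-12
        di, dj, dist_sq = di[keep], dj[keep], dist_sq[keep]
        ia = np.nonzero(aligned)[0]
        best = np.full(ia.size, np.inf)
        chunk = max(1, int(4e6 // max(ia.size, 1)))
        for k0 in range(0, di.size, chunk):
            sl = slice(k0, k0 + chunk)
            cand = fine[ci[ia][:, None] + di[sl][None, :], cj[ia][:, None] + dj[sl][None, :]]
            g2 = _gamma_sq(
                dist_sq[sl][None, :], cand, dref[ia][:, None], beta[ia][:, None], dta
            )
            best = np.minimum(best, g2.min(axis=1))
        out[ia] = np.sqrt(best)

    for p in np.nonzero(~aligned)[0]:
        j0 = np.searchsorted(fx, xr[p] - radius, side="left")
        j1 = np.searchsorted(fx, xr[p] + radius, side="right")
        i0 = np.searchsorted(neg_fy, -(yr[p] + radius), side="left")
        i1 = np.searchsorted(neg_fy, -(yr[p] - radius), side="right")
        if j0 >= j1 or i0 >= i1:
            # search disc entirely off the evaluated plane: fall back to the
            # nearest evaluated point so gamma stays defined
            jn = int(np.clip(np.rint(cjf[p]), 0, nx - 1))
            in_ = int(np.clip(np.rint(cif[p]), 0, ny - 1))
            d2 = (fx[jn] - xr[p]) ** 2 + (fy[in_] - yr[p]) ** 2
            out[p] = float(
                np.sqrt(_gamma_sq(d2, fine[in_, jn], dref[p], beta[p], dta))
            )
            continue
        sub = fine[i0:i1, j0:j1]
        dxs = fx[j0:j1] - xr[p]
        dys = fy[i0:i1] - yr[p]
        d2 = dys[:, None] ** 2 + dxs[None, :] ** 2
        inside = d2 <= radius**2 + 1e-12
        if not inside.any():
            k = np.unravel_index(np.argmin(d2), d2.shape)
            out[p] = float(
                np.sqrt(_gamma_sq(d2[k], sub[k], dref[p], beta[p], dta))
            )
            continue
        g2 = _gamma_sq(d2[inside], sub[inside], dref[p], beta[p], dta)
        out[p] = float(np.sqrt(g2.min()))
    return out
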
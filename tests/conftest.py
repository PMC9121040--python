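"""Shared fixtures and the independent brute-force gamma oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from mlcopt import DosePlane, GammaCriteria


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_plane(rng, nrows=None, ncols=None, spacing=1.0, base=100.0):
    """A random smooth-ish dose plane for property tests."""
    nrows = nrows or int(rng.integers(5, 31))
    ncols = ncols or int(rng.integers(5, 31))
    values = base * (0.2 + 0.8 * rng.random((nrows, ncols)))
    return DosePlane(values, spacing, spacing,
                     origin_x=-spacing * (ncols - 1) / 2,
                     origin_y=spacing * (nrows - 1) / 2)


def gamma_bruteforce(reference: DosePlane, evaluated: DosePlane,
                     criteria: GammaCriteria, upsample_factor: int = 10):
    """Exhaustive-search gamma: bilinear upsampling of the evaluated plane
    via scipy's grid interpolator and a minimum over *all* upsampled points,
    with no search-radius cutoff.  Independent of the package's search
    implementation."""
    dnorm = (criteria.norm_dose if criteria.norm_dose is not None
             else float(reference.values.max()))
    mask = reference.values >= criteria.threshold * dnorm

    step_x = evaluated.spacing_x / upsample_factor
    step_y = evaluated.spacing_y / upsample_factor
    ny, nx = evaluated.values.shape
    fx = evaluated.origin_x + step_x * np.arange((nx - 1) * upsample_factor + 1)
    fy = evaluated.origin_y - step_y * np.arange((ny - 1) * upsample_factor + 1)
    # interpolate in (row, col) index space to sidestep descending y
    interp = RegularGridInterpolator(
        (np.arange(ny), np.arange(nx)), evaluated.values, method="linear")
    ri = (evaluated.origin_y - fy) / evaluated.spacing_y
    ci = (fx - evaluated.origin_x) / evaluated.spacing_x
    RR, CC = np.meshgrid(np.clip(ri, 0, ny - 1), np.clip(ci, 0, nx - 1),
                         indexing="ij")
    fine = interp(np.stack([RR.ravel(), CC.ravel()], axis=1)).reshape(RR.shape)

    XX, YY = np.meshgrid(fx, fy[:, None].ravel(), indexing="xy")
    flat_x = XX.ravel()
    flat_y = YY.ravel()
    flat_d = fine.ravel()

    gamma_map = np.full(reference.values.shape, np.nan)
    beta = criteria.dd * dnorm
    for i, j in zip(*np.nonzero(mask)):
        xr = reference.origin_x + reference.spacing_x * j
        yr = reference.origin_y - reference.spacing_y * i
        dref = reference.values[i, j]
        dist_sq = (flat_x - xr) ** 2 + (flat_y - yr) ** 2
        b = beta if criteria.normalization == "global" else criteria.dd * dref
        diff = flat_d - dref
        with np.errstate(divide="ignore", invalid="ignore"):
            dose_sq = np.where(diff == 0.0, 0.0, (diff / b) ** 2)
        gamma_map[i, j] = np.sqrt(
            np.min(dist_sq / criteria.dta**2 + dose_sq))
    return gamma_map, mask
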
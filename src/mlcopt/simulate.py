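"""Synthetic dose-plane simulator for MLC deliveries.

The simulator stands in for a treatment planning system plus delivery and
measurement: it turns an MLC delivery pattern into a 2D dose plane as a
deterministic function of two machine parameters,

* **DLG** (dosimetric leaf gap, mm): every open leaf gap is widened by the
  DLG, implemented exactly as beam models do it — each leaf tip is retracted
  by half the DLG;
* **transmission** (fraction): dose leaking through closed leaves.

The dose model is a time-integrated fluence: for each point inside the jaw
opening, the fraction of delivery time the point is uncovered (computed
exactly for piecewise-linear leaf trajectories) plus ``transmission`` times
the covered fraction, convolved with a Gaussian penumbra kernel and scaled
by the monitor units.  For a sweeping gap of width g and travel L this gives
the closed form used by the LoSasso-style DLG measurement:

    D(center) = mu * [ (g + DLG)/L + T * (1 - (g + DLG)/L) ]

Tongue-and-groove, interleaf leakage and rounded-leaf-end spectral effects
are deliberately not modeled; transmission is a single scalar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import DEFAULTS
from .planes import DosePlane, GeometryError, ValidationError

__all__ = [
    "MLCModel",
    "DeliveryPattern",
    "MeasurementModel",
    "DlgEstimate",
    "open_field",
    "static_blocked",
    "sweeping_gap",
    "chair",
    "as_trajectories",
    "apply_leaf_shift",
    "simulate_plane",
    "measure_plane",
    "estimate_dlg_sweeping_gap",
    "default_toy_patterns",
]

log = logging.getLogger("mlcopt.simulate")

PATTERN_KINDS = ("open_field", "static_blocked", "sweeping_gap", "chair", "trajectories")


@dataclass(frozen=True)
class MLCModel:
    """Machine truth or model under test: DLG (mm), transmission (fraction)
    and a Gaussian penumbra scale (mm)."""

    dlg: float = 0.0
    transmission: float = 0.0
    penumbra_sigma: float = DEFAULTS.penumbra_sigma_mm

    def __post_init__(self) -> None:
        if not 0 <= self.dlg <= 5:
            raise ValidationError(f"dlg must be in [0, 5] mm, got {self.dlg}")
        if not 0 <= self.transmission <= 0.05:
            raise ValidationError(
                f"transmission must be in [0, 0.05], got {self.transmission}"
            )
        if self.penumbra_sigma < 0:
            raise ValidationError("penumbra_sigma must be >= 0")


@dataclass
class DeliveryPattern:
    """An MLC delivery.

    Parametric kinds (open_field, static_blocked, sweeping_gap, chair) carry
    their geometry in ``field_size``/``gap``/``sweep_extent``; the
    ``trajectories`` kind stores explicit per-leaf piecewise-linear tip
    positions: ``fractions`` (K monotone delivery fractions in [0, 1]) and
    ``bank_a``/``bank_b`` of shape (n_leaves, K), bank A approaching from
    -x and bank B from +x, open interval (a, b).  Leaf l spans
    ``leaf_edges[l] .. leaf_edges[l+1]`` in y (descending edges, top first).
    """

    kind: str
    field_size: tuple[float, float] = (60.0, 60.0)
    gap: Optional[float] = None
    sweep_extent: float = DEFAULTS.sweep_extent_mm
    leaf_pitch: float = 5.0
    mu: float = 100.0
    fractions: Optional[np.ndarray] = None
    bank_a: Optional[np.ndarray] = None
    bank_b: Optional[np.ndarray] = None
    leaf_edges: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise ValidationError(f"unknown pattern kind {self.kind!r}")
        if self.leaf_pitch <= 0:
            raise ValidationError("leaf_pitch must be > 0")
        if self.mu <= 0:
            raise ValidationError("mu must be > 0")
        if self.kind == "sweeping_gap":
            if self.gap is None or self.gap <= 0:
                raise ValidationError("sweeping_gap requires gap > 0")
            if self.sweep_extent < self.gap:
                raise ValidationError("sweep_extent must be >= gap")
        if self.kind == "trajectories":
            for name in ("fractions", "bank_a", "bank_b", "leaf_edges"):
                if getattr(self, name) is None:
                    raise ValidationError(f"trajectories pattern requires {name}")
            self.fractions = np.asarray(self.fractions, dtype=float)
            self.bank_a = np.asarray(self.bank_a, dtype=float)
            self.bank_b = np.asarray(self.bank_b, dtype=float)
            self.leaf_edges = np.asarray(self.leaf_edges, dtype=float)
            if np.any(np.diff(self.fractions) <= 0):
                raise ValidationError("fractions must be strictly increasing")
            if self.bank_a.shape != self.bank_b.shape or self.bank_a.shape[1] != self.fractions.size:
                raise ValidationError("bank arrays must be (n_leaves, len(fractions))")
            if np.any(self.bank_b - self.bank_a < -1e-12):
                raise ValidationError("bank_b must be >= bank_a everywhere")


@dataclass(frozen=True)
class MeasurementModel:
    """Detector-array measurement: pitch (mm), additive Gaussian noise as a
    fraction of the plane maximum, and the RNG seed."""

    grid_spacing: float = DEFAULTS.detector_pitch_mm
    noise_sd: float = 0.0
    seed: int = DEFAULTS.seed

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValidationError("grid_spacing must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# pattern constructors
# ---------------------------------------------------------------------------

def open_field(field_size=(60.0, 60.0), mu=100.0, leaf_pitch=5.0) -> DeliveryPattern:
    return DeliveryPattern("open_field", field_size=field_size, mu=mu, leaf_pitch=leaf_pitch)


def static_blocked(field_size=(60.0, 60.0), mu=100.0, leaf_pitch=5.0) -> DeliveryPattern:
    return DeliveryPattern("static_blocked", field_size=field_size, mu=mu, leaf_pitch=leaf_pitch)


def sweeping_gap(
    gap: float,
    sweep_extent: float = DEFAULTS.sweep_extent_mm,
    height: float = 60.0,
    mu: float = 100.0,
    leaf_pitch: float = 5.0,
) -> DeliveryPattern:
    return DeliveryPattern(
        "sweeping_gap",
        field_size=(sweep_extent, height),
        gap=gap,
        sweep_extent=sweep_extent,
        mu=mu,
        leaf_pitch=leaf_pitch,
    )


def chair(field_size=(60.0, 60.0), gap: float = 2.5, mu: float = 100.0,
          leaf_pitch: float = 5.0) -> DeliveryPattern:
    """Three-region commissioning pattern: one region seen only through
    closed leaves (transmission-dominated), one crossed by a narrow sweeping
    gap (DLG-dominated) and one briefly opened.

    The open region is exposed for only ~12% of the delivery, as in heavily
    modulated sliding-window fields; that keeps the plane maximum low enough
    that the transmission region clears the usual 10% analysis threshold —
    each region then genuinely informs one parameter."""
    return DeliveryPattern("chair", field_size=field_size, gap=gap, mu=mu,
                           leaf_pitch=leaf_pitch)


def _leaf_edges(height: float, pitch: float) -> np.ndarray:
    n = max(1, int(round(height / pitch)))
    return height / 2 - (height / n) * np.arange(n + 1)


def as_trajectories(pattern: DeliveryPattern) -> DeliveryPattern:
    """Explicit per-leaf piecewise-linear trajectory form of any pattern."""
    if pattern.kind == "trajectories":
        return pattern
    w, h = pattern.field_size
    edges = _leaf_edges(h, pattern.leaf_pitch)
    n = edges.size - 1
    if pattern.kind == "open_field":
        f = np.array([0.0, 1.0])
        a = np.full((n, 2), -w / 2)
        b = np.full((n, 2), w / 2)
    elif pattern.kind == "static_blocked":
        # all leaf pairs closed, abutment parked off-field on the +x side
        f = np.array([0.0, 1.0])
        park = w / 2 + 50.0
        a = np.full((n, 2), park)
        b = np.full((n, 2), park)
    elif pattern.kind == "sweeping_gap":
        g, L = pattern.gap, pattern.sweep_extent
        f = np.array([0.0, 1.0])
        a = np.tile([-L / 2, L / 2], (n, 1))
        b = a + g
    elif pattern.kind == "chair":
        g = pattern.gap if pattern.gap else 2.5
        x1, x2, x3 = -w / 6, w / 6, w / 2   # region boundaries
        # closed over [x_min, x1] throughout; gap sweeps [x1, x2] during the
        # first 65%; closed dwell; [x2+4, x3] exposed for the final ~11%.
        # The 4 mm guard band keeps the swept and open regions from
        # overlapping once the DLG widens the gap.
        guard = 4.0
        f = np.array([0.0, 0.65, 0.66, 0.88, 0.89, 1.0])
        a_row = np.array([x1 - g, x2 - g, x2, x2, x2 + guard, x2 + guard])
        b_row = np.array([x1, x2, x2, x2, x3, x3])
        a = np.tile(a_row, (n, 1))
        b = np.tile(b_row, (n, 1))
    else:  # pragma: no cover
        raise ValidationError(f"cannot expand pattern kind {pattern.kind!r}")
    return DeliveryPattern(
        "trajectories",
        field_size=pattern.field_size,
        leaf_pitch=pattern.leaf_pitch,
        mu=pattern.mu,
        fractions=f,
        bank_a=a,
        bank_b=b,
        leaf_edges=edges,
        meta=dict(pattern.meta, source_kind=pattern.kind,
                  gap=pattern.gap, sweep_extent=pattern.sweep_extent),
    )


def apply_leaf_shift(pattern: DeliveryPattern, dlg: float) -> DeliveryPattern:
    """Retract each bank-A tip by dlg/2 and each bank-B tip by dlg/2 in the
    opposite direction, widening every open gap by exactly dlg.

    This mirrors how beam models apply the DLG during dose calculation: the
    entered value moves each leaf by half of it.  ``dlg = 0`` is the
    identity.  Parametric patterns are expanded to trajectory form first.
    """
    if dlg < 0:
        raise ValidationError("dlg must be >= 0")
    if dlg == 0:
        return replace(pattern)
    traj = as_trajectories(pattern)
    return replace(
        traj,
        bank_a=traj.bank_a - dlg / 2,
        bank_b=traj.bank_b + dlg / 2,
        meta=dict(traj.meta, dlg_shift_mm=dlg),
    )


# ---------------------------------------------------------------------------
# fluence and dose
# ---------------------------------------------------------------------------

def _open_fraction_row(x: np.ndarray, f: np.ndarray, a: np.ndarray,
                       b: np.ndarray) -> np.ndarray:
    """Exact time fraction each x is inside the open interval (a(t), b(t))
    for piecewise-linear a, b over delivery fractions f."""
    total = np.zeros_like(x)
    for k in range(f.size - 1):
        df = f[k + 1] - f[k]
        a0, a1 = a[k], a[k + 1]
        b0, b1 = b[k], b[k + 1]
        da, db = a1 - a0, b1 - b0
        # s in [0,1] parametrizes the segment; a(s) < x  and  b(s) > x
        with np.errstate(divide="ignore", invalid="ignore"):
            sa = (x - a0) / da if da != 0 else None
            sb = (x - b0) / db if db != 0 else None
        if da > 0:
            lo_a, hi_a = np.zeros_like(x), np.clip(sa, 0.0, 1.0)
        elif da < 0:
            lo_a, hi_a = np.clip(sa, 0.0, 1.0), np.ones_like(x)
        else:
            open_a = (x > a0).astype(float)
            lo_a, hi_a = np.zeros_like(x), open_a
        if db > 0:
            lo_b, hi_b = np.clip(sb, 0.0, 1.0), np.ones_like(x)
        elif db < 0:
            lo_b, hi_b = np.zeros_like(x), np.clip(sb, 0.0, 1.0)
        else:
            open_b = (x < b0).astype(float)
            lo_b, hi_b = np.zeros_like(x), open_b
        lo = np.maximum(lo_a, lo_b)
        hi = np.minimum(hi_a, hi_b)
        total += np.clip(hi - lo, 0.0, 1.0) * df
    return total


def fluence_map(pattern: DeliveryPattern, machine: MLCModel, x: np.ndarray,
                y: np.ndarray) -> np.ndarray:
    """Relative fluence (open fraction + transmission under closed leaves)
    on the (y, x) grid, zero outside the jaw opening."""
    traj = apply_leaf_shift(as_trajectories(pattern), machine.dlg)
    w, h = traj.field_size
    out = np.zeros((y.size, x.size))
    in_x = (x >= -w / 2) & (x <= w / 2)
    edges = traj.leaf_edges  # descending
    for l in range(edges.size - 1):
        rows = (y <= edges[l]) & (y >= edges[l + 1]) if l == edges.size - 2 \
            else (y <= edges[l]) & (y > edges[l + 1])
        if not rows.any():
            continue
        phi = _open_fraction_row(x, traj.fractions, traj.bank_a[l], traj.bank_b[l])
        row_fluence = phi + machine.transmission * (1.0 - phi)
        out[np.ix_(rows, in_x)] = row_fluence[in_x]
    return out


def simulate_plane(
    pattern: DeliveryPattern,
    machine: MLCModel,
    spacing: float = 1.0,
    extent: float = 60.0,
) -> DosePlane:
    """Deterministic dose plane for a delivery pattern and machine model.

    The plane is a centred square of side ``extent`` mm sampled every
    ``spacing`` mm; dose is linear in the pattern's monitor units.
    """
    if spacing <= 0:
        raise ValidationError("spacing must be > 0")
    w, h = pattern.field_size
    if extent < w or extent < h:
        raise GeometryError(
            f"extent {extent} mm does not cover the {w} x {h} mm field"
        )
    half = extent / 2
    n = int(round(extent / spacing)) + 1
    x = -half + spacing * np.arange(n)
    y = half - spacing * np.arange(n)  # row 0 on top
    if machine.penumbra_sigma > 0:
        # blur on a supersampled lattice (pixel <= sigma/4) so the discrete
        # convolution approximates the continuous one independently of the
        # requested pitch, then stride back down
        s = max(1, int(np.ceil(4 * spacing / machine.penumbra_sigma)))
        fine = spacing / s
        nf = (n - 1) * s + 1
        xf = -half + fine * np.arange(nf)
        yf = half - fine * np.arange(nf)
        fl = fluence_map(pattern, machine, xf, yf)
        fl = gaussian_filter(fl, sigma=machine.penumbra_sigma / fine, mode="constant")
        fl = fl[::s, ::s]
    else:
        fl = fluence_map(pattern, machine, x, y)
    return DosePlane(
        pattern.mu * fl,
        spacing_x=spacing,
        spacing_y=spacing,
        origin_x=float(x[0]),
        origin_y=float(y[0]),
        meta={"pattern": pattern.kind, "dlg": machine.dlg,
              "transmission": machine.transmission},
    )


def measure_plane(true_plane: DosePlane, mm: MeasurementModel) -> DosePlane:
    """Detector-array measurement of a plane: block-average resampling to
    the detector pitch plus seeded additive Gaussian noise.

    With zero noise and matching pitch the measurement is the identity.
    Negative noisy readings are clipped to zero.
    """
    p = mm.grid_spacing
    if abs(p - true_plane.spacing_x) < 1e-12 and abs(p - true_plane.spacing_y) < 1e-12:
        values = true_plane.values.copy()
        out = true_plane.copy()
    else:
        x = true_plane.x
        y = true_plane.y
        cx = (x[0] + x[-1]) / 2
        cy = (y[0] + y[-1]) / 2
        mx = int(np.floor((x[-1] - cx) / p))
        my = int(np.floor((y[0] - cy) / p))
        if 2 * mx + 1 < 2 or 2 * my + 1 < 2:
            raise GeometryError(
                f"detector pitch {p} mm too coarse for plane extent "
                f"{x[-1] - x[0]:.1f} x {y[0] - y[-1]:.1f} mm"
            )
        ix = np.rint((x - cx) / p).astype(int)
        iy = np.rint((cy - y) / p).astype(int)
        keep_x = np.abs(ix) <= mx
        keep_y = np.abs(iy) <= my
        nx, ny = 2 * mx + 1, 2 * my + 1
        sums = np.zeros((ny, nx))
        counts = np.zeros((ny, nx))
        ii = (iy[keep_y] + my)[:, None] * nx + (ix[keep_x] + mx)[None, :]
        np.add.at(sums.ravel(), ii.ravel(),
                  true_plane.values[np.ix_(keep_y, keep_x)].ravel())
        np.add.at(counts.ravel(), ii.ravel(), 1.0)
        values = sums / np.maximum(counts, 1.0)
        out = DosePlane(
            values,
            spacing_x=p,
            spacing_y=p,
            origin_x=float(cx - mx * p),
            origin_y=float(cy + my * p),
            depth=true_plane.depth,
            meta=dict(true_plane.meta),
        )
        values = out.values
    if mm.noise_sd > 0:
        rng = np.random.default_rng(mm.seed)
        scale = mm.noise_sd * float(true_plane.values.max())
        values = np.clip(values + rng.normal(0.0, scale, values.shape), 0.0, None)
    out.values = values
    out.meta["measurement_seed"] = mm.seed
    out.meta["noise_sd"] = mm.noise_sd
    return out


# ---------------------------------------------------------------------------
# sweeping-gap DLG estimation (LoSasso-style)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DlgEstimate:
    """Result of the sweeping-gap fit: the gap offset (mm), the fitted line,
    and a flag for physically suspect (negative) estimates."""

    dlg_mm: float
    slope: float
    intercept: float
    suspect: bool


def estimate_dlg_sweeping_gap(
    readings: Sequence[tuple[float, float]],
    transmission: float,
    open_reading: float,
    sweep_extent: float = DEFAULTS.sweep_extent_mm,
) -> DlgEstimate:
    """Estimate the DLG from sweeping-gap readings at several gap widths.

    Each reading at nominal gap g follows
    ``R = open * [(g + dlg)/L + T * (1 - (g + dlg)/L)]``.  The transmission
    contribution is removed exactly, ``R_corr = (R - T*open) / (1 - T)``,
    which leaves ``R_corr = open * (g + dlg) / L``; a least-squares line of
    R_corr versus g then has x-intercept at ``-dlg``, and the negated
    intercept is returned.  ``transmission`` is the separately measured
    value, not a fitted one.
    """
    readings = [(float(g), float(r)) for g, r in readings]
    if len(readings) < 2:
        raise ValidationError("need at least two sweeping-gap readings")
    gaps = np.array([g for g, _ in readings])
    vals = np.array([r for _, r in readings])
    if np.any(vals <= 0):
        raise ValidationError("all readings must be positive")
    if open_reading <= 0:
        raise ValidationError("open_reading must be positive")
    if not 0 <= transmission < 1:
        raise ValidationError("transmission must be in [0, 1)")
    if np.ptp(gaps) == 0:
        raise ValidationError("all gap values are equal: fit is singular")
    corr = (vals - transmission * open_reading) / (1.0 - transmission)
    slope, intercept = np.polyfit(gaps, corr, 1)
    if slope == 0:
        raise ValidationError("zero slope: readings carry no gap dependence")
    dlg = float(intercept / slope)
    suspect = dlg < 0
    if suspect:
        log.warning("sweeping-gap fit returned negative DLG %.4f mm "
                    "(physically suspect)", dlg)
    return DlgEstimate(dlg, float(slope), float(intercept), suspect)


def default_toy_patterns(mu: float = 100.0) -> dict[str, DeliveryPattern]:
    """The desk-scale plan set used for optimizer validation: two sweeping
    gaps with different gap-to-sweep ratios plus the three-region chair."""
    return {
        "sweep5": sweeping_gap(5.0, mu=mu),
        "sweep10": sweeping_gap(10.0, mu=mu),
        "chair": chair(mu=mu),
    }
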
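"""The (DLG, transmission) phase space.

For each plan, a "calculated" dose plane exists (or can be simulated) at
every point of a rectangular grid of DLG and transmission values; comparing
each against the plan's measured plane with the gamma engine yields one
(pass rate, mean gamma) record per plan per grid point.  The resulting table
is the surface the optimizer interpolates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .config import DEFAULTS
from .gamma import GammaCriteria, compute_gamma
from .planes import DegenerateInputError, DosePlane, ValidationError
from .simulate import (
    DeliveryPattern,
    MeasurementModel,
    MLCModel,
    measure_plane,
    simulate_plane,
)

__all__ = [
    "ParameterGrid",
    "PhaseSpaceTable",
    "CompletenessError",
    "build_default_grid",
    "evaluate_phase_space",
    "simulated_plan_set",
]

log = logging.getLogger("mlcopt.phase_space")

PlanProvider = Callable[[float, float], DosePlane]


class CompletenessError(RuntimeError):
    """A calculated plane is missing for one or more grid points."""


@dataclass(frozen=True)
class ParameterGrid:
    """Ordered DLG values (mm) and transmission values (fraction)."""

    dlg_values: np.ndarray
    transmission_values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "dlg_values",
                           np.asarray(self.dlg_values, dtype=float))
        object.__setattr__(self, "transmission_values",
                           np.asarray(self.transmission_values, dtype=float))
        d, t = self.dlg_values, self.transmission_values
        if d.size < 2 or t.size < 2:
            raise ValidationError("grid needs at least 2 values per axis")
        if np.any(np.diff(d) <= 0) or np.any(np.diff(t) <= 0):
            raise ValidationError("grid values must be strictly increasing")
        if d[0] < 0 or d[-1] > 2.5:
            raise ValidationError("dlg grid must lie within [0, 2.5] mm")
        if t[0] < 0.0001 - 1e-12 or t[-1] > 0.025 + 1e-12:
            raise ValidationError("transmission grid must lie within [0.0001, 0.025]")

    def __len__(self) -> int:
        return self.dlg_values.size * self.transmission_values.size

    @property
    def bounds(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """((dlg_min, dlg_max), (t_min, t_max))."""
        return (
            (float(self.dlg_values[0]), float(self.dlg_values[-1])),
            (float(self.transmission_values[0]), float(self.transmission_values[-1])),
        )

    def pairs(self):
        """All (dlg, transmission) pairs, dlg-major order."""
        for d in self.dlg_values:
            for t in self.transmission_values:
                yield float(d), float(t)


def build_default_grid() -> ParameterGrid:
    """The standard clinical search grid: DLG from 0 to 2.5 mm in 0.05 mm
    steps (51 values) and transmission {0.01%} then 0.25% to 2.5% in 0.25%
    steps (11 values), 561 pairs in total."""
    dlg = np.round(np.linspace(0.0, 2.5, 51), 10)
    trans = np.round(np.concatenate([[0.0001], 0.0025 * np.arange(1, 11)]), 10)
    return ParameterGrid(dlg, trans)


@dataclass
class PhaseSpaceTable:
    """Per plan x grid point gamma statistics.

    ``data`` columns: plan_id, dlg_mm, transmission (fraction), pass_rate,
    mean_gamma; rows in canonical (plan_id, dlg, transmission) order.
    """

    data: pd.DataFrame
    grid: ParameterGrid
    criteria: GammaCriteria
    provenance: dict = field(default_factory=dict)
    _surface_cache: dict = field(default_factory=dict, repr=False)

    COLUMNS = ("plan_id", "dlg_mm", "transmission", "pass_rate", "mean_gamma")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValidationError(f"table missing columns {sorted(missing)}")
        self.data = (
            self.data.loc[:, list(self.COLUMNS)]
            .sort_values(["plan_id", "dlg_mm", "transmission"], kind="mergesort")
            .reset_index(drop=True)
        )
        counts = self.data.groupby("plan_id").size()
        if (counts != len(self.grid)).any():
            bad = counts[counts != len(self.grid)]
            raise ValidationError(
                f"incomplete table: plans with wrong record count: {dict(bad)}"
            )

    @property
    def plan_ids(self) -> list[str]:
        return sorted(self.data["plan_id"].unique())

    def surface(self, plan_id: str, metric: str) -> np.ndarray:
        """Metric values on the grid, shape (n_dlg, n_transmission)."""
        if metric not in ("pass_rate", "mean_gamma"):
            raise ValidationError(f"unknown metric {metric!r}")
        key = (plan_id, metric)
        if key not in self._surface_cache:
            sub = self.data[self.data["plan_id"] == plan_id]
            if sub.empty:
                raise KeyError(f"plan {plan_id!r} not in table")
            nd = self.grid.dlg_values.size
            nt = self.grid.transmission_values.size
            # canonical order is dlg-major, transmission-minor
            self._surface_cache[key] = sub[metric].to_numpy().reshape(nd, nt)
        return self._surface_cache[key]

    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV (transmission in percent) with a JSON
        sidecar holding grid, criteria and provenance."""
        path = Path(path)
        out = self.data.copy()
        out["transmission_pct"] = out.pop("transmission") * 100.0
        out = out[["plan_id", "dlg_mm", "transmission_pct", "pass_rate", "mean_gamma"]]
        with open(path, "w") as fh:
            fh.write(out.to_csv(index=False, float_format="%.12g",
                                lineterminator="\n"))
        sidecar = {
            "grid": {
                "dlg_values_mm": self.grid.dlg_values.tolist(),
                "transmission_values": self.grid.transmission_values.tolist(),
            },
            "criteria": {
                "dta_mm": self.criteria.dta,
                "dd": self.criteria.dd,
                "threshold": self.criteria.threshold,
                "normalization": self.criteria.normalization,
                "norm_dose": self.criteria.norm_dose,
            },
            "provenance": self.provenance,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhaseSpaceTable":
        path = Path(path)
        df = pd.read_csv(path)
        df["transmission"] = df.pop("transmission_pct") / 100.0
        side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        grid = ParameterGrid(
            np.asarray(side["grid"]["dlg_values_mm"]),
            np.asarray(side["grid"]["transmission_values"]),
        )
        c = side["criteria"]
        criteria = GammaCriteria(
            dta=c["dta_mm"], dd=c["dd"], threshold=c["threshold"],
            normalization=c["normalization"], norm_dose=c["norm_dose"],
        )
        return cls(df, grid, criteria, side.get("provenance", {}))


def _plane_digest(plane: DosePlane) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(plane.values).tobytes())
    h.update(np.array([plane.spacing_x, plane.spacing_y,
                       plane.origin_x, plane.origin_y]).tobytes())
    return h.hexdigest()[:16]


def evaluate_phase_space(
    plans: Mapping[str, tuple[PlanProvider, DosePlane]],
    grid: ParameterGrid,
    criteria: GammaCriteria = GammaCriteria(),
    search_factor: float = DEFAULTS.search_factor,
    upsample_factor: int = DEFAULTS.upsample_factor,
) -> PhaseSpaceTable:
    """Gamma statistics for every plan at every grid point.

    ``plans`` maps plan id to (provider, measured plane), the provider
    yielding the calculated plane for a (dlg, transmission) pair.  Records
    are independent of evaluation order; rows are stored in canonical order.
    A grid point whose plane cannot be produced is a completeness error
    (all gaps listed); a degenerate gamma input is recorded as NaN and
    logged, never silently dropped.
    """
    rows = []
    gaps: list[tuple[str, float, float, str]] = []
    for plan_id in sorted(plans):
        provider, measured = plans[plan_id]
        for dlg, trans in grid.pairs():
            try:
                calc = provider(dlg, trans)
            except Exception as exc:  # missing plane
                gaps.append((plan_id, dlg, trans, str(exc)))
                continue
            try:
                res = compute_gamma(measured, calc, criteria,
                                    search_factor=search_factor,
                                    upsample_factor=upsample_factor)
                pr, mg = res.pass_rate, res.mean_gamma
            except DegenerateInputError as exc:
                log.error("degenerate gamma input for plan %s at "
                          "(dlg=%.3f, T=%.4f): %s", plan_id, dlg, trans, exc)
                pr, mg = np.nan, np.nan
            rows.append((plan_id, dlg, trans, pr, mg))
    if gaps:
        listing = "; ".join(
            f"{p} (dlg={d:.3f} mm, T={t:.4f}): {m}" for p, d, t, m in gaps[:20]
        )
        raise CompletenessError(
            f"{len(gaps)} calculated plane(s) missing: {listing}"
        )
    df = pd.DataFrame(rows, columns=list(PhaseSpaceTable.COLUMNS))
    provenance = {
        plan_id: {"measured_digest": _plane_digest(plans[plan_id][1]),
                  "measured_meta": {k: v for k, v in plans[plan_id][1].meta.items()
                                    if isinstance(v, (int, float, str, bool))}}
        for plan_id in sorted(plans)
    }
    return PhaseSpaceTable(df, grid, criteria, provenance)


def simulated_plan_set(
    patterns: Mapping[str, DeliveryPattern],
    truth: MLCModel,
    measurement: MeasurementModel,
    calc_spacing: float = 2.0,
    true_spacing: float | None = None,
    extent: float = 60.0,
) -> dict[str, tuple[PlanProvider, DosePlane]]:
    """Simulator-backed plan set: the measured plane of each pattern comes
    from the truth machine passed through the measurement model, and the
    provider simulates the calculated plane for any requested
    (dlg, transmission) at the TPS export spacing.

    The truth plane is simulated at ``true_spacing`` (default 1 mm) so the
    penumbra blur is well resolved; diode arrays then sample the delivered
    dose essentially at points, so when the detector pitch is an integer
    multiple of ``true_spacing`` the measured plane is the truth sampled on
    the detector lattice plus noise.  Otherwise block-average resampling
    via :func:`measure_plane` is used."""
    if true_spacing is None:
        true_spacing = 1.0

    def make_provider(pat: DeliveryPattern) -> PlanProvider:
        def provider(dlg: float, trans: float) -> DosePlane:
            machine = MLCModel(dlg, trans, truth.penumbra_sigma)
            return simulate_plane(pat, machine, spacing=calc_spacing, extent=extent)
        return provider

    pitch = measurement.grid_spacing
    stride = pitch / true_spacing
    out: dict[str, tuple[PlanProvider, DosePlane]] = {}
    for name in sorted(patterns):
        pat = patterns[name]
        true_plane = simulate_plane(pat, truth, spacing=true_spacing, extent=extent)
        if abs(stride - round(stride)) < 1e-9 and round(stride) >= 1:
            k = int(round(stride))
            sampled = DosePlane(
                true_plane.values[::k, ::k],
                spacing_x=pitch,
                spacing_y=pitch,
                origin_x=true_plane.origin_x,
                origin_y=true_plane.origin_y,
                depth=true_plane.depth,
                meta=dict(true_plane.meta),
            )
            measured = measure_plane(sampled, measurement)
        else:
            measured = measure_plane(true_plane, measurement)
        out[name] = (make_provider(pat), measured)
    return out
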
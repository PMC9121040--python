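"""Readers and writers for dose planes, delivery patterns and plan manifests.

Supported plane formats:

* **DICOM RT Dose** — the interchange format treatment planning systems
  export.  Dose is stored as scaled integers (``DoseGridScaling``), geometry
  in ``PixelSpacing`` / ``ImagePositionPatient`` / ``ImageOrientationPatient``.
* **ASCII grid** — an open, bit-auditable text dialect used as the
  measurement interchange format (array exports from commercial QA software
  are proprietary).  Seven ``key value`` header lines (``rows``, ``cols``,
  ``spacing_x_mm``, ``spacing_y_mm``, ``origin_x_mm``, ``origin_y_mm``,
  ``units cGy``) followed by whitespace-separated dose rows, top row =
  largest y; ``#`` lines are comments.  Round trips are lossless at full
  float precision.

Plan manifests (YAML) bind plan ids to measured planes and to either a
calculated-plane path template over the parameter grid or a simulator
pattern with truth parameters.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pydicom
import yaml
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .config import DEFAULTS
from .gamma import GammaCriteria
from .planes import DosePlane, ValidationError
from .simulate import (
    DeliveryPattern,
    MeasurementModel,
    MLCModel,
    measure_plane,
    simulate_plane,
)

__all__ = [
    "FormatError",
    "read_rtdose",
    "write_rtdose",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_plane",
    "write_plane",
    "read_pattern",
    "write_pattern",
    "PlanManifest",
    "ManifestEntry",
    "load_manifest",
    "manifest_plan_set",
]

log = logging.getLogger("mlcopt.io")

RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"


class FormatError(ValueError):
    """A file does not conform to its format; the message names the file
    and the offending attribute or line."""


# ---------------------------------------------------------------------------
# DICOM RT Dose
# ---------------------------------------------------------------------------

def _deterministic_uid(payload: bytes, root: str = DEFAULTS.uid_root) -> str:
    digest = int.from_bytes(hashlib.sha256(payload).digest()[:12], "big")
    return (root + str(digest))[:64]


def read_rtdose(path: str | Path, frame: Optional[int] = None) -> DosePlane:
    """Read a 2D dose plane from a DICOM RT Dose file, in cGy.

    Multi-frame objects require an explicit ``frame`` selection.
    """
    path = Path(path)
    ds = pydicom.dcmread(path)
    for attr in ("DoseGridScaling", "PixelSpacing", "ImagePositionPatient"):
        if getattr(ds, attr, None) is None:
            raise FormatError(f"{path}: missing required attribute {attr}")
    arr = ds.pixel_array
    nframes = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if arr.ndim == 3 or nframes > 1:
        if frame is None:
            raise FormatError(
                f"{path}: multi-frame dose ({nframes} frames) requires an "
                "explicit frame selection"
            )
        arr = arr[frame]
    values = arr.astype(float) * float(ds.DoseGridScaling)
    units = str(getattr(ds, "DoseUnits", "GY")).upper()
    if units == "GY":
        values = values * 100.0
    elif units != "CGY":
        raise FormatError(f"{path}: unsupported DoseUnits {units!r}")
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)
    ipp = [float(v) for v in ds.ImagePositionPatient]
    iop = [float(v) for v in getattr(ds, "ImageOrientationPatient",
                                     [1, 0, 0, 0, -1, 0])]
    if np.allclose(iop, [1, 0, 0, 0, -1, 0]):
        origin_y = ipp[1]
    elif np.allclose(iop, [1, 0, 0, 0, 1, 0]):
        # rows ascend in y: flip into the package convention (row 0 on top)
        values = values[::-1]
        origin_y = ipp[1] + (values.shape[0] - 1) * row_spacing
    else:
        raise FormatError(
            f"{path}: unsupported ImageOrientationPatient {iop}"
        )
    return DosePlane(
        values,
        spacing_x=col_spacing,
        spacing_y=row_spacing,
        origin_x=ipp[0],
        origin_y=origin_y,
        meta={"source": str(path), "sop_instance_uid": str(getattr(ds, "SOPInstanceUID", ""))},
    )


def write_rtdose(plane: DosePlane, path: str | Path) -> None:
    """Write a plane as a single-frame DICOM RT Dose file (dose in Gy,
    uint32 pixels).

    The dose-grid scaling maps the plane maximum near the top of the
    integer range, so quantization error is at most half a scaling step.
    UIDs are derived deterministically from the content: identical planes
    produce identical bytes.
    """
    path = Path(path)
    values_gy = plane.values / 100.0
    vmax = float(values_gy.max())
    scaling = vmax / (2**32 - 1) if vmax > 0 else 1.0
    # quantize with the value that will actually be stored (DS strings cap
    # at 16 bytes), clipping guards the last-bin rounding overflow
    scaling = float(f"{scaling:.10e}")
    pixels = np.clip(np.rint(values_gy / scaling), 0, 2**32 - 1).astype(np.uint32)

    payload = pixels.tobytes() + np.array(
        [plane.spacing_x, plane.spacing_y, plane.origin_x, plane.origin_y]
    ).tobytes()

    fm = FileMetaDataset()
    fm.MediaStorageSOPClassUID = RTDOSE_SOP_CLASS
    fm.MediaStorageSOPInstanceUID = _deterministic_uid(payload + b"sop")
    fm.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = fm
    ds.SOPClassUID = RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = fm.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.PatientName = "PHANTOM^QA"
    ds.PatientID = "MLCOPT"
    ds.FrameOfReferenceUID = _deterministic_uid(payload + b"for")
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.Rows, ds.Columns = plane.values.shape
    ds.PixelSpacing = [f"{plane.spacing_y:.10g}", f"{plane.spacing_x:.10g}"]
    ds.ImagePositionPatient = [f"{plane.origin_x:.10g}", f"{plane.origin_y:.10g}", "0"]
    ds.ImageOrientationPatient = ["1", "0", "0", "0", "-1", "0"]
    ds.NumberOfFrames = 1
    ds.GridFrameOffsetVector = [0.0]
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = f"{scaling:.10e}"  # DS values cap at 16 bytes
    ds.PixelData = pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# ASCII grid
# ---------------------------------------------------------------------------

_ASCII_HEADER_KEYS = (
    "rows", "cols", "spacing_x_mm", "spacing_y_mm",
    "origin_x_mm", "origin_y_mm", "units",
)


def read_ascii_grid(path: str | Path) -> DosePlane:
    """Read the ASCII grid dialect (see module docstring)."""
    path = Path(path)
    header: dict[str, str] = {}
    data_rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(header) < len(_ASCII_HEADER_KEYS):
                if len(parts) != 2 or parts[0] not in _ASCII_HEADER_KEYS:
                    raise FormatError(
                        f"{path}:{lineno}: expected header 'key value' line "
                        f"({', '.join(k for k in _ASCII_HEADER_KEYS if k not in header)} "
                        f"missing), got {line!r}"
                    )
                if parts[0] in header:
                    raise FormatError(f"{path}:{lineno}: duplicate header key {parts[0]!r}")
                header[parts[0]] = parts[1]
                continue
            try:
                data_rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad dose value: {exc}") from None
    if len(header) < len(_ASCII_HEADER_KEYS):
        raise FormatError(f"{path}: incomplete header, got keys {sorted(header)}")
    if header["units"] != "cGy":
        raise FormatError(f"{path}: unsupported units {header['units']!r}")
    rows, cols = int(header["rows"]), int(header["cols"])
    if len(data_rows) != rows:
        raise FormatError(
            f"{path}: header says {rows} rows but found {len(data_rows)}"
        )
    for i, r in enumerate(data_rows):
        if len(r) != cols:
            raise FormatError(
                f"{path}: data row {i + 1} has {len(r)} values, expected {cols}"
            )
    return DosePlane(
        np.array(data_rows),
        spacing_x=float(header["spacing_x_mm"]),
        spacing_y=float(header["spacing_y_mm"]),
        origin_x=float(header["origin_x_mm"]),
        origin_y=float(header["origin_y_mm"]),
        meta={"source": str(path)},
    )


def write_ascii_grid(plane: DosePlane, path: str | Path) -> None:
    """Write the ASCII grid dialect at full float precision (lossless)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# mlcopt dose plane: mm coordinates, isocenter at (0,0), "
                 "leaf motion along x, y increasing upward;\n"
                 "# origin is the centre of the top-left pixel, "
                 "top row = largest y.\n")
        fh.write(f"rows {plane.values.shape[0]}\n")
        fh.write(f"cols {plane.values.shape[1]}\n")
        fh.write(f"spacing_x_mm {plane.spacing_x:.17g}\n")
        fh.write(f"spacing_y_mm {plane.spacing_y:.17g}\n")
        fh.write(f"origin_x_mm {plane.origin_x:.17g}\n")
        fh.write(f"origin_y_mm {plane.origin_y:.17g}\n")
        fh.write("units cGy\n")
        for row in plane.values:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_plane(path: str | Path) -> DosePlane:
    """Dispatch on extension: .dcm -> DICOM RT Dose, else ASCII grid."""
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        return read_rtdose(path)
    return read_ascii_grid(path)


def write_plane(plane: DosePlane, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        write_rtdose(plane, path)
    else:
        write_ascii_grid(plane, path)


# ---------------------------------------------------------------------------
# delivery patterns (YAML/JSON-compatible schema)
# ---------------------------------------------------------------------------

def pattern_to_dict(pattern: DeliveryPattern) -> dict:
    out = {
        "kind": pattern.kind,
        "field_size_mm": list(pattern.field_size),
        "leaf_pitch_mm": pattern.leaf_pitch,
        "mu": pattern.mu,
    }
    if pattern.gap is not None:
        out["gap_mm"] = pattern.gap
    if pattern.kind == "sweeping_gap":
        out["sweep_extent_mm"] = pattern.sweep_extent
    if pattern.kind == "trajectories":
        out["fractions"] = pattern.fractions.tolist()
        out["bank_a_mm"] = pattern.bank_a.tolist()
        out["bank_b_mm"] = pattern.bank_b.tolist()
        out["leaf_edges_mm"] = pattern.leaf_edges.tolist()
    return out


def pattern_from_dict(d: dict) -> DeliveryPattern:
    try:
        kind = d["kind"]
    except KeyError:
        raise FormatError("pattern is missing 'kind'") from None
    kwargs = dict(
        kind=kind,
        field_size=tuple(d.get("field_size_mm", (60.0, 60.0))),
        leaf_pitch=float(d.get("leaf_pitch_mm", 5.0)),
        mu=float(d.get("mu", 100.0)),
    )
    if "gap_mm" in d:
        kwargs["gap"] = float(d["gap_mm"])
    if "sweep_extent_mm" in d:
        kwargs["sweep_extent"] = float(d["sweep_extent_mm"])
    if kind == "trajectories":
        for src, dst in (("fractions", "fractions"), ("bank_a_mm", "bank_a"),
                         ("bank_b_mm", "bank_b"), ("leaf_edges_mm", "leaf_edges")):
            if src not in d:
                raise FormatError(f"trajectories pattern missing {src!r}")
            kwargs[dst] = np.asarray(d[src], dtype=float)
    return DeliveryPattern(**kwargs)


def read_pattern(path: str | Path) -> DeliveryPattern:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise FormatError(f"{path}: pattern file must hold a mapping")
    try:
        return pattern_from_dict(d)
    except (FormatError, ValidationError) as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_pattern(pattern: DeliveryPattern, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(pattern_to_dict(pattern), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# plan manifests
# ---------------------------------------------------------------------------

@dataclass
class ManifestEntry:
    """One plan: a measured plane (file or simulated from truth parameters)
    plus a source of calculated planes (path template or pattern)."""

    plan_id: str
    measured_path: Optional[Path] = None
    calculated_template: Optional[str] = None
    pattern: Optional[DeliveryPattern] = None
    truth_dlg_mm: Optional[float] = None
    truth_transmission: Optional[float] = None


@dataclass
class PlanManifest:
    entries: list[ManifestEntry]
    criteria: GammaCriteria
    seed: int = DEFAULTS.seed
    measurement: MeasurementModel = field(
        default_factory=MeasurementModel
    )
    penumbra_sigma: float = DEFAULTS.penumbra_sigma_mm
    base_dir: Path = Path(".")


def load_manifest(path: str | Path) -> PlanManifest:
    """Load and validate a YAML plan manifest.

    Every problem is collected and reported together, not just the first.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    problems: list[str] = []
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: manifest must be a mapping")

    c = doc.get("criteria", {}) or {}
    try:
        criteria = GammaCriteria(
            dta=float(c.get("dta_mm", DEFAULTS.dta_mm)),
            dd=float(c.get("dd_pct", DEFAULTS.dd_fraction * 100)) / 100.0,
            threshold=float(c.get("threshold_pct",
                                  DEFAULTS.threshold_fraction * 100)) / 100.0,
            normalization=c.get("normalization", DEFAULTS.normalization),
            norm_dose=c.get("norm_dose_cgy"),
        )
    except ValidationError as exc:
        problems.append(f"criteria: {exc}")
        criteria = GammaCriteria()

    m = doc.get("measurement", {}) or {}
    seed = int(doc.get("seed", DEFAULTS.seed))
    try:
        measurement = MeasurementModel(
            grid_spacing=float(m.get("grid_spacing_mm", DEFAULTS.detector_pitch_mm)),
            noise_sd=float(m.get("noise_pct", 0.0)) / 100.0,
            seed=seed,
        )
    except ValidationError as exc:
        problems.append(f"measurement: {exc}")
        measurement = MeasurementModel(seed=seed)

    entries: list[ManifestEntry] = []
    seen: set[str] = set()
    base = path.parent
    for i, item in enumerate(doc.get("plans") or []):
        tag = f"plans[{i}]"
        if not isinstance(item, dict) or "plan_id" not in item:
            problems.append(f"{tag}: missing plan_id")
            continue
        pid = str(item["plan_id"])
        tag = f"plan {pid!r}"
        if pid in seen:
            problems.append(f"{tag}: duplicate plan_id")
            continue
        seen.add(pid)
        entry = ManifestEntry(plan_id=pid)
        has_pattern = "pattern" in item
        if "measured" in item:
            p = base / str(item["measured"])
            if not p.exists():
                problems.append(f"{tag}: measured plane not found: {p}")
            entry.measured_path = p
        elif not has_pattern:
            problems.append(f"{tag}: needs 'measured' or 'pattern'")
        if "calculated_template" in item:
            entry.calculated_template = str(item["calculated_template"])
        if has_pattern:
            pat = item["pattern"]
            try:
                entry.pattern = (read_pattern(base / pat) if isinstance(pat, str)
                                 else pattern_from_dict(pat))
            except (FormatError, ValidationError) as exc:
                problems.append(f"{tag}: bad pattern: {exc}")
            truth = item.get("truth", {}) or {}
            entry.truth_dlg_mm = float(truth.get("dlg_mm", 0.0))
            entry.truth_transmission = float(truth.get("transmission_pct", 0.0)) / 100.0
        elif "calculated_template" not in item:
            problems.append(f"{tag}: needs 'calculated_template' or 'pattern'")
        entries.append(entry)
    if not entries:
        problems.append("manifest lists no plans")
    if problems:
        raise FormatError(
            f"{path}: {len(problems)} problem(s):\n  " + "\n  ".join(problems)
        )
    return PlanManifest(
        entries=entries,
        criteria=criteria,
        seed=seed,
        measurement=measurement,
        penumbra_sigma=float(doc.get("penumbra_sigma_mm",
                                     DEFAULTS.penumbra_sigma_mm)),
        base_dir=base,
    )


def manifest_plan_set(
    manifest: PlanManifest,
    calc_spacing: float = 2.0,
    true_spacing: float = 1.0,
    extent: float = 60.0,
):
    """Turn a manifest into the plan mapping consumed by
    ``evaluate_phase_space``: plan_id -> (provider, measured plane)."""
    plans = {}
    for entry in manifest.entries:
        if entry.measured_path is not None:
            measured = read_plane(entry.measured_path)
        else:
            truth = MLCModel(entry.truth_dlg_mm, entry.truth_transmission,
                             manifest.penumbra_sigma)
            measured = measure_plane(
                simulate_plane(entry.pattern, truth, spacing=true_spacing,
                               extent=extent),
                manifest.measurement,
            )
        if entry.calculated_template is not None:
            template = entry.calculated_template
            base = manifest.base_dir
            pid = entry.plan_id

            def provider(dlg, trans, template=template, base=base, pid=pid):
                rel = template.format(plan_id=pid, dlg=dlg,
                                      transmission=trans,
                                      transmission_pct=trans * 100.0)
                return read_plane(base / rel)
        else:
            pattern = entry.pattern
            sigma = manifest.penumbra_sigma

            def provider(dlg, trans, pattern=pattern, sigma=sigma):
                return simulate_plane(pattern, MLCModel(dlg, trans, sigma),
                                      spacing=calc_spacing, extent=extent)
        plans[entry.plan_id] = (provider, measured)
    return plans
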
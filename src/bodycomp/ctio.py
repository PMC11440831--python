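"""CT volume, label-map and annotation I/O with explicit unit conventions.

All volumes are kept in Hounsfield units with axis 0 = craniocaudal
(caudal -> cranial, 0-based, ``z_mm = slice_index * spacing_z``), axis 1 =
anteroposterior, axis 2 = left-right.  NIfTI (via nibabel) is the internal
interchange format; DICOM series (via pydicom) are import-only, with stored
values rescaled to HU through the slope/intercept tags and slices sorted
caudal -> cranial by their patient z position.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

__all__ = [
    "CTVolume",
    "TissueLabelMap",
    "AnnotationTable",
    "LABEL_BACKGROUND", "LABEL_OTHER", "LABEL_SM", "LABEL_VAT", "LABEL_SAT",
    "LABEL_NAMES",
    "load_volume", "save_volume",
    "load_label_map", "save_label_map",
    "load_annotations", "save_annotations",
    "slice_index_to_z_mm", "z_mm_to_slice_index",
]

HU_MIN, HU_MAX = -1024.0, 3071.0

LABEL_BACKGROUND = 0
LABEL_OTHER = 1
LABEL_SM = 2
LABEL_VAT = 3
LABEL_SAT = 4
LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_OTHER: "other-body",
    LABEL_SM: "SM",
    LABEL_VAT: "VAT",
    LABEL_SAT: "SAT",
}

ANNOTATION_COLUMNS = ["id", "l3_slice_index", "l3_z_mm", "spacing_z_mm", "height_m"]


class VolumeIOError(IOError):
    pass


class AnnotationSchemaError(ValueError):
    pass


def slice_index_to_z_mm(index, spacing_z_mm: float) -> float:
    """Single source of truth for the index <-> z conversion (0-based)."""
    return np.asarray(index, dtype=float) * spacing_z_mm


def z_mm_to_slice_index(z_mm, spacing_z_mm: float):
    """Inverse of :func:`slice_index_to_z_mm`, rounding half-up (cranial)."""
    return np.floor(np.asarray(z_mm, dtype=float) / spacing_z_mm + 0.5).astype(int)


@dataclass
class CTVolume:
    """A 3-D HU grid with (z, y, x) spacing in mm."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume expects a 3-D array")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def slice_z_mm(self, index: int) -> float:
        return float(slice_index_to_z_mm(index, self.spacing_mm[0]))

    def clamped(self) -> "CTVolume":
        out = int(np.sum((self.voxels < HU_MIN) | (self.voxels > HU_MAX)))
        if out:
            warnings.warn(f"clamping {out} voxels outside [{HU_MIN:.0f}, {HU_MAX:.0f}] HU")
        return CTVolume(np.clip(self.voxels, HU_MIN, HU_MAX), self.spacing_mm, self.origin_mm)


@dataclass
class TissueLabelMap:
    """Per-pixel class map for one axial slice; codes per ``LABEL_NAMES``."""

    labels: np.ndarray
    spacing_mm: tuple[float, float]  # (y, x)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("TissueLabelMap expects a 2-D array")
        bad = set(np.unique(self.labels)) - set(LABEL_NAMES)
        if bad:
            raise ValueError(f"unknown label codes: {sorted(bad)}")

    def mask(self, code: int) -> np.ndarray:
        if code not in LABEL_NAMES:
            raise ValueError(f"unknown label code {code}")
        return self.labels == code


@dataclass
class AnnotationTable:
    """One row per scan: L3 slice index / z position plus scan metadata."""

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in ANNOTATION_COLUMNS[:4] if c not in self.frame.columns]
        if missing:
            raise AnnotationSchemaError(f"missing annotation columns: {missing}")
        if self.frame["id"].duplicated().any():
            dup = self.frame.loc[self.frame["id"].duplicated(), "id"].tolist()
            raise AnnotationSchemaError(f"duplicate scan ids: {dup}")
        if (self.frame["l3_slice_index"] < 0).any():
            raise AnnotationSchemaError("l3_slice_index must be >= 0")

    def __len__(self) -> int:
        return len(self.frame)

    def row(self, scan_id) -> pd.Series:
        hit = self.frame[self.frame["id"] == scan_id]
        if hit.empty:
            raise KeyError(f"scan id {scan_id!r} not in annotation table")
        return hit.iloc[0]


# ---- volumes ----------------------------------------------------------------


def _nifti_affine(spacing_mm, origin_mm) -> np.ndarray:
    # array stored as (x, y, z) on disk; spacing given as (z, y, x)
    aff = np.diag([spacing_mm[2], spacing_mm[1], spacing_mm[0], 1.0])
    aff[:3, 3] = [origin_mm[2], origin_mm[1], origin_mm[0]]
    return aff


def save_volume(volume: CTVolume, path, dtype=np.int16) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz), int16 HU by default."""
    volume = volume.clamped()
    data = np.rint(volume.voxels).astype(dtype) if np.issubdtype(dtype, np.integer) \
        else volume.voxels.astype(dtype)
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)),
                          _nifti_affine(volume.spacing_mm, volume.origin_mm))
    img.header.set_zooms((volume.spacing_mm[2], volume.spacing_mm[1], volume.spacing_mm[0]))
    nib.save(img, str(path))


def _load_nifti(path) -> CTVolume:
    img = nib.load(str(path))
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    return CTVolume(voxels=data, spacing_mm=spacing, origin_mm=origin)


def _load_dicom_series(path) -> CTVolume:
    files = sorted(Path(path).glob("*.dcm")) or sorted(
        p for p in Path(path).iterdir() if p.is_file())
    if not files:
        raise VolumeIOError(f"no DICOM files found in {path}")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception as exc:  # unreadable DICOMs are a named, explicit failure
            raise VolumeIOError(f"problem reading DICOM file {f}: {exc}") from exc
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise VolumeIOError(f"mixed DICOM series in {path}: {sorted(map(str, uids))}")
    # sort caudal -> cranial by patient z
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = [float(ds.ImagePositionPatient[2]) for ds in datasets]
    dz = float(np.median(np.diff(zs))) if len(zs) > 1 else float(
        getattr(datasets[0], "SliceThickness", 1.0))
    rows = np.stack([
        ds.pixel_array * float(getattr(ds, "RescaleSlope", 1.0))
        + float(getattr(ds, "RescaleIntercept", 0.0))
        for ds in datasets
    ]).astype(np.float32)
    py, px = (float(v) for v in datasets[0].PixelSpacing)
    return CTVolume(voxels=rows, spacing_mm=(abs(dz), py, px),
                    origin_mm=(zs[0], 0.0, 0.0)).clamped()


def load_volume(path, format: str | None = None) -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory."""
    p = Path(path)
    if not p.exists():
        raise VolumeIOError(f"no such path: {p}")
    if format is None:
        format = "dicom" if p.is_dir() else "nifti"
    if format == "nifti":
        return _load_nifti(p)
    if format in ("dicom", "dicom-series"):
        return _load_dicom_series(p)
    raise ValueError(f"unknown format {format!r}")


# ---- label maps -------------------------------------------------------------


def save_label_map(label_map: TissueLabelMap, path) -> None:
    img = nib.Nifti1Image(
        np.transpose(label_map.labels.astype(np.uint8), (1, 0))[:, :, None],
        np.diag([label_map.spacing_mm[1], label_map.spacing_mm[0], 1.0, 1.0]))
    nib.save(img, str(path))


def load_label_map(path) -> TissueLabelMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        data = data[:, :, 0]
    zooms = img.header.get_zooms()
    return TissueLabelMap(labels=np.transpose(data, (1, 0)).astype(np.uint8),
                          spacing_mm=(float(zooms[1]), float(zooms[0])))


# ---- annotation tables ------------------------------------------------------


def load_annotations(path) -> AnnotationTable:
    """Read a CSV or XLSX annotation table.

    ``l3_z_mm`` may be absent; it is then recomputed as index * spacing.
    """
    p = Path(path)
    if p.suffix.lower() in (".xlsx", ".xls"):
        frame = pd.read_excel(p)
    else:
        frame = pd.read_csv(p)
    missing = [c for c in ("id", "l3_slice_index", "spacing_z_mm") if c not in frame.columns]
    if missing:
        raise AnnotationSchemaError(f"{p}: missing annotation columns: {missing}")
    if "l3_z_mm" not in frame.columns:
        frame["l3_z_mm"] = slice_index_to_z_mm(
            frame["l3_slice_index"].to_numpy(), 1.0) * frame["spacing_z_mm"].to_numpy()
    if "height_m" not in frame.columns:
        frame["height_m"] = np.nan
    frame = frame[ANNOTATION_COLUMNS].astype(
        {"l3_slice_index": int, "l3_z_mm": float, "spacing_z_mm": float, "height_m": float})
    return AnnotationTable(frame=frame)


def save_annotations(table: AnnotationTable, path) -> None:
    p = Path(path)
    if p.suffix.lower() in (".xlsx", ".xls"):
        table.frame.to_excel(p, index=False)
    else:
        table.frame.to_csv(p, index=False)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
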
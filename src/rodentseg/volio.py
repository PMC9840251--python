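"""Volumetric image and mask I/O.

NIfTI-1 is the on-disk format for all volumes and masks. In memory every
grid is a numpy array in (z, y, x) axis order with spacing stored as
(dz, dy, dx) in mm. Only axis-aligned scaling affines are accepted: the
whole pipeline (resampling, surface distances) assumes an axis-aligned
lattice, so rotated or sheared NIfTI affines are rejected at load time
rather than silently misinterpreted.

Case layout convention (one directory per case)::

    <case_dir>/<case_id>_T1WI.nii.gz
    <case_dir>/<case_id>_T2WI.nii.gz
    <case_dir>/<case_id>_CE-T1WI.nii.gz
    <case_dir>/<case_id>_mask-brain.nii.gz   (optional)
    <case_dir>/<case_id>_mask-tumor.nii.gz   (optional)
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("rodentseg")

MODALITIES = ("T1WI", "T2WI", "CE-T1WI")
MASK_ROLES = ("brain", "tumor")
SOURCE_STYLES = ("leuven_like", "tcia_like")

#: relative tolerance when comparing voxel spacings of two grids
SPACING_RTOL = 1e-4


class IncompleteSequenceError(FileNotFoundError):
    """A case directory lacks one or more of the required MRI sequences."""


class LatticeMismatchError(ValueError):
    """Two grids that must share a lattice differ in shape or spacing."""


def _check_lattice(shape_a, spacing_a, shape_b, spacing_b, what: str) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise LatticeMismatchError(
            f"{what}: shape mismatch {tuple(shape_a)} vs {tuple(shape_b)}"
        )
    if not np.allclose(spacing_a, spacing_b, rtol=SPACING_RTOL, atol=0.0):
        raise LatticeMismatchError(
            f"{what}: spacing mismatch {tuple(spacing_a)} vs {tuple(spacing_b)}"
        )


@dataclass
class Volume:
    """A 3-D scalar image on an axis-aligned lattice.

    Parameters
    ----------
    data:
        Intensities, float array of shape (nz, ny, nx).
    spacing:
        Voxel size (dz, dy, dx) in mm, all strictly positive.
    modality:
        One of ``T1WI``, ``T2WI``, ``CE-T1WI`` (or ``""`` for derived maps).
    case_id:
        Identifier of the case the volume belongs to.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = ""
    case_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if any(n < 2 for n in self.data.shape):
            raise ValueError(f"every axis needs >= 2 voxels, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.modality and self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains NaN/Inf intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray, spacing=None) -> "Volume":
        """Copy of this volume with new data (and optionally new spacing)."""
        return Volume(
            data=data,
            spacing=self.spacing if spacing is None else spacing,
            modality=self.modality,
            case_id=self.case_id,
        )


@dataclass
class Mask:
    """A binary {0,1} grid on the same lattice as its paired Volume."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    role: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask values must be 0/1, found {uniq[:10]}")
        self.labels = arr.astype(np.uint8)
        if self.labels.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.labels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.role and self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def count(self) -> int:
        return int(self.labels.sum())

    def is_empty(self) -> bool:
        return self.count() == 0

    def volume_mm3(self) -> float:
        return self.count() * float(np.prod(self.spacing))

    def as_bool(self) -> np.ndarray:
        return self.labels.astype(bool)

    def with_labels(self, labels: np.ndarray) -> "Mask":
        return Mask(labels=labels, spacing=self.spacing, role=self.role)


@dataclass
class ModalityStack:
    """Three co-registered volumes (T1WI, T2WI, CE-T1WI) on one lattice."""

    t1: Volume
    t2: Volume
    ce_t1: Volume

    def __post_init__(self) -> None:
        for v, m in zip(self.volumes, MODALITIES):
            if v.modality and v.modality != m:
                raise ValueError(f"channel order violated: expected {m}, got {v.modality}")
        ref = self.t1
        for other in (self.t2, self.ce_t1):
            _check_lattice(ref.shape, ref.spacing, other.shape, other.spacing,
                           "modality stack")

    @property
    def volumes(self) -> tuple[Volume, Volume, Volume]:
        return (self.t1, self.t2, self.ce_t1)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.t1.spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1.shape

    def as_array(self) -> np.ndarray:
        """Channels-first array of shape (3, nz, ny, nx), float32."""
        return np.stack([v.data for v in self.volumes]).astype(np.float32)

    @classmethod
    def from_array(cls, arr: np.ndarray, spacing, case_id: str = "") -> "ModalityStack":
        arr = np.asarray(arr)
        if arr.ndim != 4 or arr.shape[0] != 3:
            raise ValueError(f"expected (3, nz, ny, nx) array, got {arr.shape}")
        vols = [Volume(arr[i], spacing, MODALITIES[i], case_id) for i in range(3)]
        return cls(*vols)


@dataclass
class CaseRecord:
    """One case: a modality stack plus optional ground-truth masks."""

    case_id: str
    stack: ModalityStack
    brain_mask: Mask | None = None
    tumor_mask: Mask | None = None
    source_style: str = "leuven_like"

    def __post_init__(self) -> None:
        if self.source_style not in SOURCE_STYLES:
            raise ValueError(f"unknown source_style {self.source_style!r}")
        for mask, name in ((self.brain_mask, "brain mask"),
                           (self.tumor_mask, "tumor mask")):
            if mask is not None:
                _check_lattice(self.stack.shape, self.stack.spacing,
                               mask.shape, mask.spacing, f"{self.case_id} {name}")


# ---------------------------------------------------------------------------
# NIfTI round-trip
# ---------------------------------------------------------------------------

def _spacing_from_affine(affine: np.ndarray, path) -> tuple[float, float, float]:
    """Extract (dz, dy, dx) from a scaling affine; reject rotations/shears."""
    rot = affine[:3, :3]
    scales = np.sqrt((rot ** 2).sum(axis=0))
    if np.any(scales <= 0):
        raise ValueError(f"{path}: degenerate affine scales {scales}")
    # off-diagonal mass relative to the scale signals rotation/shear
    off = np.abs(rot) - np.diag(np.abs(np.diag(rot)))
    if np.any(np.abs(off) > 1e-3 * scales.max()):
        raise ValueError(
            f"{path}: non-axis-aligned affine (rotation/shear); this pipeline "
            "requires axis-aligned grids"
        )
    # nibabel data axes are (x, y, z); we store (z, y, x)
    dx, dy, dz = scales
    return (float(dz), float(dy), float(dx))


def read_volume(path: str | os.PathLike, modality: str = "",
                case_id: str = "") -> Volume:
    """Read a NIfTI file into a Volume with (z, y, x) axis order.

    Raises FileNotFoundError for a missing file, ValueError for non-3D
    images, NaN voxels, or non-axis-aligned affines.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {data.shape}")
    spacing = _spacing_from_affine(img.affine, path)
    data = np.ascontiguousarray(np.transpose(data, (2, 1, 0)), dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: image contains NaN/Inf voxels")
    return Volume(data=data, spacing=spacing, modality=modality, case_id=case_id)


def read_mask(path: str | os.PathLike, role: str = "") -> Mask:
    """Read a NIfTI mask; any nonzero voxel is coerced to 1 (warned)."""
    v = read_volume(path)
    labels = v.data
    nonbinary = ~np.isin(labels, (0.0, 1.0))
    if nonbinary.any():
        logger.warning("%s: %d non-binary voxels coerced to 1",
                       path, int(nonbinary.sum()))
    return Mask(labels=(labels != 0).astype(np.uint8), spacing=v.spacing, role=role)


def _affine_from_spacing(spacing) -> np.ndarray:
    dz, dy, dx = spacing
    aff = np.diag([dx, dy, dz, 1.0])
    return aff


def write_volume(v: Volume | Mask, path: str | os.PathLike) -> Path:
    """Write a Volume (float32) or Mask (uint8) as NIfTI-1.

    Re-reading reproduces the data bit-exactly and the spacing to header
    float precision.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if isinstance(v, Mask):
        data, spacing = v.labels.astype(np.uint8), v.spacing
    else:
        data, spacing = v.data.astype(np.float32), v.spacing
    # back to nibabel (x, y, z) order
    out = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    img = nib.Nifti1Image(out, _affine_from_spacing(spacing))
    img.header.set_zooms(tuple(float(s) for s in spacing[::-1]))
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Case assembly
# ---------------------------------------------------------------------------

def modality_path(case_dir: str | os.PathLike, case_id: str, modality: str) -> Path:
    return Path(case_dir) / f"{case_id}_{modality}.nii.gz"


def mask_path(case_dir: str | os.PathLike, case_id: str, role: str) -> Path:
    return Path(case_dir) / f"{case_id}_mask-{role}.nii.gz"


def load_case(case_dir: str | os.PathLike, case_id: str,
              source_style: str = "leuven_like") -> CaseRecord:
    """Assemble a validated CaseRecord from a case directory.

    All three modalities must be present; masks are optional. Any lattice
    mismatch between modalities or masks raises LatticeMismatchError.
    """
    case_dir = Path(case_dir)
    missing = [m for m in MODALITIES
               if not modality_path(case_dir, case_id, m).exists()]
    if missing:
        raise IncompleteSequenceError(
            f"case {case_id!r} in {case_dir}: incomplete sequence, "
            f"missing {', '.join(missing)}"
        )
    vols = [read_volume(modality_path(case_dir, case_id, m), m, case_id)
            for m in MODALITIES]
    stack = ModalityStack(*vols)
    masks: dict[str, Mask | None] = {}
    for role in MASK_ROLES:
        p = mask_path(case_dir, case_id, role)
        masks[role] = read_mask(p, role) if p.exists() else None
    return CaseRecord(case_id=case_id, stack=stack,
                      brain_mask=masks["brain"], tumor_mask=masks["tumor"],
                      source_style=source_style)


def save_case(rec: CaseRecord, case_dir: str | os.PathLike) -> Path:
    """Write a CaseRecord in the standard case layout, creating the dir."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    for v, m in zip(rec.stack.volumes, MODALITIES):
        write_volume(v, modality_path(case_dir, rec.case_id, m))
    if rec.brain_mask is not None:
        write_volume(rec.brain_mask, mask_path(case_dir, rec.case_id, "brain"))
    if rec.tumor_mask is not None:
        write_volume(rec.tumor_mask, mask_path(case_dir, rec.case_id, "tumor"))
    return case_dir


def validate_case(case_dir: str | os.PathLike, case_id: str) -> dict:
    """Per-case completeness/lattice report used by ``rodentseg validate``."""
    report: dict = {"case_id": case_id, "complete": False, "error": None}
    try:
        rec = load_case(case_dir, case_id)
    except (IncompleteSequenceError, LatticeMismatchError, ValueError) as exc:
        report["error"] = str(exc)
        return report
    report["complete"] = True
    report["shape"] = rec.stack.shape
    report["spacing_mm"] = rec.stack.spacing
    report["has_brain_mask"] = rec.brain_mask is not None
    report["has_tumor_mask"] = rec.tumor_mask is not None
    return report
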
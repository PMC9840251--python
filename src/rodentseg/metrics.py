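"""Segmentation evaluation: DSC, RV, MSD, HD.

The four measures reported for every prediction/ground-truth pair:

- Dice similarity coefficient  DSC = 2|P∩G| / (|P| + |G|), by integer
  voxel counts.
- Volume ratio  RV(seg1, seg2) = V1 / V2 with physical volumes; reports
  use (prediction, ground truth) order.
- Mean surface distance  MSD = (Σ_p d(p, S') + Σ_p' d(p', S)) / (n_S + n_S'),
  the symmetric mean of minimum Euclidean point-to-surface distances.
- Hausdorff distance  HD = max{ sup_x d(x, Y), sup_y d(X, y) }, the exact
  symmetric Hausdorff distance (100th percentile, not HD95).

Surfaces are the centers of foreground voxels with at least one background
6-neighbor (out-of-grid counts as background), in physical mm by default;
a voxel-unit mode exists because surface distances are not comparable
across grids with different voxel sizes.

Empty-mask conventions: DSC is 1 when both masks are empty and 0 when
exactly one is; RV and the surface metrics are flagged undefined (NaN)
whenever they would divide by zero or need an empty surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volio import Mask, _check_lattice

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class SurfacePointSet:
    """Boundary voxel centers in physical coordinates (mm or voxels)."""

    points: np.ndarray  # (n, 3)
    units: str = "mm"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) == 0:
            raise ValueError("surface point set may not be empty")

    @property
    def count(self) -> int:
        return len(self.points)


@dataclass
class MetricReport:
    """The four-number evaluation record for one segmentation pair."""

    dsc: float
    rv: float
    msd: float
    hd: float
    units: str = "mm"
    rv_defined: bool = True
    surface_defined: bool = True

    def as_dict(self) -> dict:
        return {"dsc": self.dsc, "rv": self.rv, "msd": self.msd, "hd": self.hd,
                "units": self.units, "rv_defined": self.rv_defined,
                "surface_defined": self.surface_defined}


def _require_lattice(a: Mask, b: Mask) -> None:
    _check_lattice(a.shape, a.spacing, b.shape, b.spacing, "metric operands")


def dice_coefficient(p: Mask, g: Mask) -> float:
    """DSC by integer voxel counts; 1 if both empty (warned), 0 if one is."""
    _require_lattice(p, g)
    np_, ng = p.count(), g.count()
    if np_ == 0 and ng == 0:
        import logging
        logging.getLogger("rodentseg").warning(
            "DSC of two empty masks defined as 1 by convention")
        return 1.0
    inter = int(np.logical_and(p.as_bool(), g.as_bool()).sum())
    return 2.0 * inter / (np_ + ng)


def volume_ratio(seg1: Mask, seg2: Mask) -> float:
    """RV = V1/V2 with physical volumes; NaN (warned) when seg2 is empty."""
    _require_lattice(seg1, seg2)
    if seg2.count() == 0:
        import logging
        logging.getLogger("rodentseg").warning(
            "volume ratio undefined for empty reference segmentation")
        return float("nan")
    return seg1.volume_mm3() / seg2.volume_mm3()


def extract_surface(m: Mask, units: str = "mm") -> SurfacePointSet:
    """Boundary voxels = foreground voxels with a background 6-neighbor
    (the grid border counts as background). Coordinates are voxel centers
    scaled by spacing when units="mm"."""
    if m.is_empty():
        raise ValueError("cannot extract the surface of an empty mask")
    fg = m.as_bool()
    interior = ndimage.binary_erosion(fg, structure=_STRUCT6, border_value=0)
    boundary = fg & ~interior
    idx = np.argwhere(boundary).astype(np.float64)
    if units == "mm":
        idx *= np.asarray(m.spacing)
    elif units != "voxel":
        raise ValueError(f"unknown units {units!r}")
    return SurfacePointSet(points=idx, units=units)


def _directed_min_dists(a: SurfacePointSet, b: SurfacePointSet) -> np.ndarray:
    """d(p, B) for every p in A, via a k-d tree."""
    tree = cKDTree(b.points)
    d, _ = tree.query(a.points, k=1)
    return d


def mean_surface_distance(s: SurfacePointSet, s2: SurfacePointSet) -> float:
    """Symmetric MSD: (Σ d(p,S') + Σ d(p',S)) / (n_S + n_S')."""
    d_ab = _directed_min_dists(s, s2)
    d_ba = _directed_min_dists(s2, s)
    return float((d_ab.sum() + d_ba.sum()) / (s.count + s2.count))


def hausdorff_distance(x: SurfacePointSet, y: SurfacePointSet) -> float:
    """Exact symmetric Hausdorff distance between two point sets."""
    d_xy = _directed_min_dists(x, y)
    d_yx = _directed_min_dists(y, x)
    return float(max(d_xy.max(), d_yx.max()))


def evaluate_pair(pred: Mask, truth: Mask, units: str = "mm") -> MetricReport:
    """Compute all four metrics for one (prediction, ground truth) pair.

    Surface metrics are NaN with ``surface_defined=False`` when either
    mask is empty; RV is NaN with ``rv_defined=False`` when the ground
    truth is empty.
    """
    _require_lattice(pred, truth)
    dsc = dice_coefficient(pred, truth)
    rv_defined = truth.count() > 0
    rv = volume_ratio(pred, truth) if rv_defined else float("nan")
    surface_defined = pred.count() > 0 and truth.count() > 0
    if surface_defined:
        sp = extract_surface(pred, units)
        sg = extract_surface(truth, units)
        msd = mean_surface_distance(sp, sg)
        hd = hausdorff_distance(sp, sg)
    else:
        msd = hd = float("nan")
    return MetricReport(dsc=dsc, rv=rv, msd=msd, hd=hd, units=units,
                        rv_defined=rv_defined, surface_defined=surface_defined)
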
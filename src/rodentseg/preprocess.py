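"""Preprocessing and augmentation chain.

Order of operations for network input mirrors the training recipe:
intensity normalization, isotropic resampling to 0.5 mm by cubic B-spline
interpolation, central crop/pad to a patch-divisible matrix, stacking of
the three modalities, and tiling into non-overlapping 64^3 patches.
Augmentation draws from the group generated by in-plane 90-degree
rotations and vertical/horizontal flips — exact lattice permutations,
never interpolated.

Masks travel through the same geometric chain but are resampled with
nearest-neighbor interpolation by default to preserve binarity (a
linear-interpolation + 0.5-threshold mode is available via
``mask_mode="linear"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import Mask, ModalityStack, Volume

DEFAULT_TARGET_MM = 0.5
DEFAULT_PATCH = 64


# ---------------------------------------------------------------------------
# Intensity normalization
# ---------------------------------------------------------------------------

def normalize_intensity(v: Volume, mode: str = "zscore") -> Volume:
    """Normalize voxel intensities.

    ``zscore`` maps to zero mean / unit SD (the network-input default);
    ``minmax255`` maps [min, max] -> [0, 255] (used by the noise protocol).
    A constant volume is an error under zscore and an all-zero volume
    (with a warning) under minmax255.
    """
    data = v.data.astype(np.float64)
    lo, hi = float(data.min()), float(data.max())
    if mode == "zscore":
        sd = float(data.std())
        if sd == 0.0 or lo == hi:
            raise ValueError("zscore normalization of a constant volume")
        out = (data - data.mean()) / sd
    elif mode == "minmax255":
        if hi == lo:
            import logging
            logging.getLogger("rodentseg").warning(
                "minmax255 on constant volume -> all zeros")
            out = np.zeros_like(data)
        else:
            out = (data - lo) * (255.0 / (hi - lo))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return v.with_data(out.astype(np.float32))


# ---------------------------------------------------------------------------
# Isotropic resampling
# ---------------------------------------------------------------------------

def _resample_array(data: np.ndarray, spacing, target_mm: float,
                    order: int) -> np.ndarray:
    in_shape = data.shape
    out_shape = tuple(max(1, int(np.rint(n * s / target_mm)))
                      for n, s in zip(in_shape, spacing))
    # output voxel j sits at physical j*target_mm; input voxel i at i*s.
    grids = [np.arange(m, dtype=np.float64) * target_mm / s
             for m, s in zip(out_shape, spacing)]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    out = ndimage.map_coordinates(data.astype(np.float64), [zz, yy, xx],
                                  order=order, mode="nearest")
    return out, out_shape


def resample_isotropic(v: Volume, target_mm: float = DEFAULT_TARGET_MM,
                       order: int = 3) -> Volume:
    """Resample a volume to an isotropic lattice (cubic B-spline default).

    Output dimensions are ``round(dim * spacing / target_mm)`` per axis,
    each at least 1.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be > 0")
    out, _ = _resample_array(v.data, v.spacing, target_mm, order)
    return Volume(out.astype(np.float32), (target_mm,) * 3, v.modality, v.case_id)


def resample_mask_isotropic(m: Mask, target_mm: float = DEFAULT_TARGET_MM,
                            mask_mode: str = "nearest") -> Mask:
    """Resample a mask; nearest-neighbor by default, or linear + 0.5
    threshold with ``mask_mode="linear"``. Output values stay in {0, 1}."""
    if target_mm <= 0:
        raise ValueError("target_mm must be > 0")
    if mask_mode == "nearest":
        out, _ = _resample_array(m.labels, m.spacing, target_mm, order=0)
        labels = out.astype(np.uint8)
    elif mask_mode == "linear":
        out, _ = _resample_array(m.labels.astype(np.float64), m.spacing,
                                 target_mm, order=1)
        labels = (out >= 0.5).astype(np.uint8)
    else:
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    return Mask(labels, (target_mm,) * 3, m.role)


# ---------------------------------------------------------------------------
# Central crop / pad
# ---------------------------------------------------------------------------

def _crop_or_pad_array(data: np.ndarray, target_shape, pad_value=0.0) -> np.ndarray:
    """Center data in a grid of target_shape, cropping or zero-padding per
    axis independently. When the difference is odd the extra voxel goes to
    the high-index side."""
    out = data
    for ax, (n, t) in enumerate(zip(data.shape, target_shape)):
        if t < 1:
            raise ValueError("target dims must be >= 1")
        if t < out.shape[ax]:
            start = (out.shape[ax] - t) // 2
            sl = [slice(None)] * out.ndim
            sl[ax] = slice(start, start + t)
            out = out[tuple(sl)]
        elif t > out.shape[ax]:
            before = (t - out.shape[ax]) // 2
            after = t - out.shape[ax] - before
            pads = [(0, 0)] * out.ndim
            pads[ax] = (before, after)
            out = np.pad(out, pads, constant_values=pad_value)
    return out


def central_crop_or_pad(v: Volume | Mask, target_shape) -> Volume | Mask:
    """Centered crop (when larger) or zero-pad (when smaller), per axis."""
    target_shape = tuple(int(t) for t in target_shape)
    if isinstance(v, Mask):
        return v.with_labels(_crop_or_pad_array(v.labels, target_shape, 0))
    return v.with_data(_crop_or_pad_array(v.data, target_shape, 0.0))


def preprocess_stack(stack: ModalityStack, target_mm: float = DEFAULT_TARGET_MM,
                     target_shape=None, normalize: str = "zscore") -> ModalityStack:
    """Full image chain: normalize -> resample -> central crop/pad."""
    vols = []
    for v in stack.volumes:
        if normalize:
            v = normalize_intensity(v, normalize)
        v = resample_isotropic(v, target_mm)
        if target_shape is not None:
            v = central_crop_or_pad(v, target_shape)
        vols.append(v)
    return ModalityStack(*vols)


def preprocess_mask(m: Mask, target_mm: float = DEFAULT_TARGET_MM,
                    target_shape=None, mask_mode: str = "nearest") -> Mask:
    m = resample_mask_isotropic(m, target_mm, mask_mode)
    if target_shape is not None:
        m = central_crop_or_pad(m, target_shape)
    return m


# ---------------------------------------------------------------------------
# Patchify / unpatchify
# ---------------------------------------------------------------------------

@dataclass
class PatchGrid:
    """Non-overlapping tiling of a (C, nz, ny, nx) array into cubes."""

    patches: list[np.ndarray]
    origins: list[tuple[int, int, int]]
    source_shape: tuple[int, int, int]
    patch: int

    def __post_init__(self) -> None:
        seen = set()
        n_expected = 1
        for d in self.source_shape:
            if d % self.patch:
                raise ValueError(
                    f"source shape {self.source_shape} not divisible by "
                    f"patch {self.patch}; crop/pad first")
            n_expected *= d // self.patch
        for o in self.origins:
            if o in seen:
                raise ValueError(f"overlapping patch origin {o}")
            if any(c % self.patch or c + self.patch > d
                   for c, d in zip(o, self.source_shape)):
                raise ValueError(f"origin {o} does not tile {self.source_shape}")
            seen.add(o)
        if len(self.origins) != n_expected or len(self.patches) != n_expected:
            raise ValueError("origins do not cover the source grid exactly")


def patchify(arr: np.ndarray | ModalityStack, patch: int = DEFAULT_PATCH) -> PatchGrid:
    """Tile a stack (or (C, nz, ny, nx) array) into non-overlapping
    patch^3 blocks. Every dimension must be divisible by ``patch``."""
    if isinstance(arr, ModalityStack):
        arr = arr.as_array()
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[None]
    shape = arr.shape[1:]
    for d in shape:
        if d % patch:
            raise ValueError(
                f"dims {shape} not divisible by patch {patch}; apply "
                "central_crop_or_pad first")
    patches, origins = [], []
    for z in range(0, shape[0], patch):
        for y in range(0, shape[1], patch):
            for x in range(0, shape[2], patch):
                patches.append(np.ascontiguousarray(
                    arr[:, z:z + patch, y:y + patch, x:x + patch]))
                origins.append((z, y, x))
    return PatchGrid(patches=patches, origins=origins,
                     source_shape=shape, patch=patch)


def unpatchify(grid: PatchGrid) -> np.ndarray:
    """Exact inverse of patchify: reassemble patches (data or per-patch
    probability maps) at their origins."""
    c = grid.patches[0].shape[0]
    out = np.zeros((c,) + tuple(grid.source_shape), dtype=grid.patches[0].dtype)
    p = grid.patch
    for block, (z, y, x) in zip(grid.patches, grid.origins):
        out[:, z:z + p, y:y + p, x:x + p] = block
    return out


# ---------------------------------------------------------------------------
# Augmentation (exact lattice permutations)
# ---------------------------------------------------------------------------

def _rot90_axes(axis: int) -> tuple[int, int]:
    """Plane of rotation for a rotation about ``axis`` (z=0, y=1, x=2)."""
    return tuple(a for a in (0, 1, 2) if a != axis)


def apply_ops(arr: np.ndarray, ops) -> np.ndarray:
    """Apply a sequence of ("flip", axis) / ("rot90", axis, k) ops to a
    3-D array (or to the spatial axes of a (C, nz, ny, nx) array)."""
    arr = np.asarray(arr)
    spatial_offset = arr.ndim - 3
    out = arr
    for op in ops:
        if op[0] == "flip":
            out = np.flip(out, axis=op[1] + spatial_offset)
        elif op[0] == "rot90":
            axis, k = op[1], op[2]
            a, b = _rot90_axes(axis)
            if k % 2 and out.shape[a + spatial_offset] != out.shape[b + spatial_offset]:
                raise ValueError(
                    f"rot90 about axis {axis} needs equal dims in plane "
                    f"({a},{b}); got {out.shape}")
            out = np.rot90(out, k=k, axes=(a + spatial_offset, b + spatial_offset))
        else:
            raise ValueError(f"unknown op {op!r}")
    return np.ascontiguousarray(out)


def random_ops(seed: int | np.random.Generator) -> list:
    """Uniform draw from the group generated by in-plane (y,x) 90-degree
    rotations and vertical/horizontal flips."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ops = [("rot90", 0, int(rng.integers(0, 4)))]
    if rng.random() < 0.5:
        ops.append(("flip", 1))
    if rng.random() < 0.5:
        ops.append(("flip", 2))
    return ops


def augment(stack: ModalityStack, m_brain: Mask | None, m_tumor: Mask | None,
            ops=None, seed: int = 0):
    """Apply one geometric transform identically to every channel and to
    both masks. ``ops`` is an explicit op list; when None, a random group
    element is drawn from ``seed``."""
    if ops is None:
        ops = random_ops(seed)
    arr = apply_ops(stack.as_array(), ops)
    out_stack = ModalityStack.from_array(arr, stack.spacing, stack.t1.case_id)
    out_brain = m_brain.with_labels(apply_ops(m_brain.labels, ops)) if m_brain else None
    out_tumor = m_tumor.with_labels(apply_ops(m_tumor.labels, ops)) if m_tumor else None
    return out_stack, out_brain, out_tumor
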
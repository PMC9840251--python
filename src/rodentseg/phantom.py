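"""Synthetic multi-modal rodent-head phantoms with ground-truth masks.

The generator emulates the two acquisition styles found in multi-center
rodent brain-tumor MRI: coronal rat scans covering the whole head on a
192x192x80 grid at 0.29x0.29x0.43 mm ("leuven_like"), and transverse
mouse scans on a 256x256x30 grid at 0.12x0.12x0.50 mm whose coverage
truncates the posterior brain ("tcia_like").

Geometry is procedural: an ellipsoidal soft-tissue head envelope, a
brighter skull shell around an ellipsoidal brain, a spherical tumor
inside one hemisphere, an optional concentric necrotic core, optional
enlarged CSF-bright lateral ventricles, and an optional midline shift of
the brain contralateral to the tumor. The intensity contract mirrors the
radiological appearance of rodent brain tumors: hyperintense on T2WI and
on CE-T1WI when well enhanced, hypointense on T1WI, with the necrotic
core suppressing contrast enhancement (perfusion deficiency).

Intensities are piecewise-constant region means, smoothed with a 1-voxel
Gaussian to create soft tissue ramps, plus additive Gaussian noise scaled
so that (brain-tissue mean) / (background SD) equals the requested SNR.
Air has mean 0 before noise, which makes that SNR definition operational.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .volio import CaseRecord, Mask, ModalityStack, save_case

STYLES = ("leuven_like", "tcia_like")

#: default grid (nz, ny, nx) and spacing (dz, dy, dx) per acquisition style
STYLE_DEFAULTS = {
    "leuven_like": {"matrix": (80, 192, 192), "spacing": (0.43, 0.29, 0.29),
                    "base_snr": 12.0},
    "tcia_like": {"matrix": (30, 256, 256), "spacing": (0.50, 0.12, 0.12),
                  "base_snr": 6.0},
}

#: region mean intensities (arbitrary units) per modality (T1WI, T2WI, CE-T1WI)
REGION_MEANS = {
    "soft_tissue": (100.0, 80.0, 100.0),
    "skull":       (140.0, 110.0, 140.0),
    "brain":       (120.0, 100.0, 120.0),
    "ventricle":   (60.0, 180.0, 60.0),
    "tumor_well":  (70.0, 160.0, 185.0),
    "tumor_poor":  (70.0, 160.0, 112.0),
    "necrosis":    (60.0, 175.0, 85.0),
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case.

    tumor_radius_frac is the tumor radius as a fraction of the smallest
    brain semi-axis, in (0, 0.9]; necrosis_frac is the necrotic-core
    radius as a fraction of the tumor radius, in [0, 0.8].
    """

    style: str = "leuven_like"
    matrix: tuple[int, int, int] | None = None
    spacing: tuple[float, float, float] | None = None
    tumor_radius_frac: float = 0.4
    necrosis_frac: float = 0.0
    ventriculomegaly: bool = False
    midline_shift_mm: float = 0.0
    enhancement: str = "well"
    base_snr: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.style not in STYLES:
            raise ValueError(f"unknown style {self.style!r}")
        defaults = STYLE_DEFAULTS[self.style]
        if self.matrix is None:
            self.matrix = defaults["matrix"]
        if self.spacing is None:
            self.spacing = defaults["spacing"]
        if self.base_snr is None:
            self.base_snr = defaults["base_snr"]
        self.matrix = tuple(int(n) for n in self.matrix)
        self.spacing = tuple(float(s) for s in self.spacing)
        if not (0.0 < self.tumor_radius_frac <= 0.9):
            raise ValueError(
                f"tumor_radius_frac must be in (0, 0.9], got {self.tumor_radius_frac}")
        if not (0.0 <= self.necrosis_frac <= 0.8):
            raise ValueError(
                f"necrosis_frac must be in [0, 0.8], got {self.necrosis_frac}")
        if self.midline_shift_mm < 0:
            raise ValueError("midline_shift_mm must be >= 0")
        if self.enhancement not in ("well", "poor"):
            raise ValueError(f"enhancement must be 'well' or 'poor'")
        if self.base_snr <= 0:
            raise ValueError("base_snr must be > 0")


@dataclass
class PhantomCase:
    record: CaseRecord
    spec: PhantomSpec

    def __post_init__(self) -> None:
        bm, tm = self.record.brain_mask, self.record.tumor_mask
        if bm is None or tm is None:
            raise ValueError("phantom cases carry both ground-truth masks")
        if np.any(tm.labels > bm.labels):
            raise ValueError("tumor mask must be contained in brain mask")


def _physical_grid(matrix, spacing):
    """Voxel-center coordinates (mm) per axis, origin at voxel (0,0,0)."""
    return [np.arange(n, dtype=np.float64) * s for n, s in zip(matrix, spacing)]


def _ellipsoid(coords, center, semi_axes):
    z, y, x = np.meshgrid(*coords, indexing="ij", sparse=True)
    cz, cy, cx = center
    az, ay, ax = semi_axes
    return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one phantom case; deterministic given ``spec.seed``."""
    nz, ny, nx = spec.matrix
    coords = _physical_grid(spec.matrix, spec.spacing)
    extent = np.array([c[-1] for c in coords])  # physical size per axis (mm)
    center = extent / 2.0

    # Head envelope; tcia_like grids truncate the head in z (posterior
    # brain outside coverage), emulated by elongating head/brain along z
    # past the grid boundary.
    head_ax = 0.46 * extent
    brain_center = center.copy()
    if spec.style == "tcia_like":
        head_ax = head_ax.copy()
        head_ax[0] = 1.0 * extent[0]
        brain_center[0] = 0.30 * extent[0]

    head = _ellipsoid(coords, center if spec.style == "leuven_like"
                      else brain_center * np.array([1.0, 0, 0]) + center * np.array([0, 1, 1]),
                      head_ax)

    brain_ax = 0.62 * head_ax
    if spec.style == "tcia_like":
        brain_ax = brain_ax.copy()
        brain_ax[0] = 0.75 * extent[0]

    # Tumor lives in the +x hemisphere; midline shift pushes the brain
    # (with its interior structures) toward -x while the skull stays put.
    shift = np.array([0.0, 0.0, -spec.midline_shift_mm])
    skull_outer = _ellipsoid(coords, brain_center, brain_ax * 1.16)
    skull_inner = _ellipsoid(coords, brain_center, brain_ax * 1.04)
    skull = skull_outer & ~skull_inner

    brain = _ellipsoid(coords, brain_center + shift, brain_ax) & skull_inner

    tumor_radius = spec.tumor_radius_frac * brain_ax.min()
    tumor_radius = max(tumor_radius, 2.0 * min(spec.spacing))
    tumor_center = brain_center + shift + np.array([0.0, 0.0, 0.45 * brain_ax[2]])
    tumor = _ellipsoid(coords, tumor_center, (tumor_radius,) * 3) & brain
    if not tumor.any():  # extreme shift can clip the sphere; keep a valid pair
        tumor = _ellipsoid(coords, brain_center + shift, (tumor_radius,) * 3) & brain

    necrosis = np.zeros_like(tumor)
    if spec.necrosis_frac > 0:
        necrosis = _ellipsoid(coords, tumor_center,
                              (spec.necrosis_frac * tumor_radius,) * 3) & tumor

    ventricle = np.zeros_like(tumor)
    if spec.ventriculomegaly:
        v_ax = (0.30 * brain_ax[0], 0.18 * brain_ax[1], 0.10 * brain_ax[2])
        for side in (-1.0, 1.0):
            v_center = brain_center + shift + np.array(
                [0.0, 0.0, side * 0.18 * brain_ax[2]])
            ventricle |= _ellipsoid(coords, v_center, v_ax)
        ventricle &= brain & ~tumor

    # --- intensity synthesis -------------------------------------------
    region_ids = np.zeros((nz, ny, nx), dtype=np.int8)
    order = [("soft_tissue", head), ("skull", skull), ("brain", brain),
             ("ventricle", ventricle),
             ("tumor_well" if spec.enhancement == "well" else "tumor_poor", tumor),
             ("necrosis", necrosis)]
    names = [name for name, _ in order]
    for i, (_, region) in enumerate(order, start=1):
        region_ids[region] = i

    rng = np.random.default_rng(spec.seed)
    channels = []
    brain_tissue = brain & ~tumor
    for ch in range(3):
        img = np.zeros((nz, ny, nx), dtype=np.float32)
        for i, name in enumerate(names, start=1):
            img[region_ids == i] = REGION_MEANS[name][ch]
        img = gaussian_filter(img, sigma=1.0)
        tissue_mean = float(img[brain_tissue].mean()) if brain_tissue.any() else 100.0
        sigma = tissue_mean / spec.base_snr
        img = img + rng.normal(0.0, sigma, size=img.shape).astype(np.float32)
        channels.append(img.astype(np.float32))

    case_id = f"{spec.style.split('_')[0]}-{spec.seed:05d}"
    stack = ModalityStack.from_array(np.stack(channels), spec.spacing, case_id)
    record = CaseRecord(
        case_id=case_id,
        stack=stack,
        brain_mask=Mask(brain.astype(np.uint8), spec.spacing, "brain"),
        tumor_mask=Mask(tumor.astype(np.uint8), spec.spacing, "tumor"),
        source_style=spec.style,
    )
    return PhantomCase(record=record, spec=spec)


def snr_regions_from_case(case: CaseRecord, erode: int = 2):
    """Ground-truth SNR regions: tissue = brain - tumor, background = air
    eroded to avoid skull/partial-volume bleed. Returns (tissue, background)
    Masks. See robustness.compute_snr.
    """
    from scipy.ndimage import binary_erosion

    brain = case.brain_mask.as_bool()
    tumor = case.tumor_mask.as_bool() if case.tumor_mask is not None else np.zeros_like(brain)
    tissue = brain & ~tumor
    t2 = case.stack.t2.data
    # air: everything far below soft tissue; use a conservative threshold at
    # half the soft-tissue mean, then erode
    bg = t2 < 0.5 * REGION_MEANS["soft_tissue"][1]
    bg &= ~brain
    if erode > 0:
        bg = binary_erosion(bg, iterations=erode, border_value=1)
    return (Mask(tissue.astype(np.uint8), case.stack.spacing),
            Mask(bg.astype(np.uint8), case.stack.spacing))


# ---------------------------------------------------------------------------
# Dataset sampling
# ---------------------------------------------------------------------------

def sample_spec(style: str, rng: np.random.Generator,
                matrix=None, spacing=None) -> PhantomSpec:
    """Draw one spec emulating the variety described for the study data:
    various tumor sizes, with/without ventriculomegaly, with/without
    intratumoral necrosis; poor enhancement is common in the tcia_like
    style and absent in the leuven_like style."""
    necrosis = float(rng.uniform(0.3, 0.6)) if rng.random() < 0.5 else 0.0
    enhancement = "well"
    if style == "tcia_like" and rng.random() < 0.7:
        enhancement = "poor"
    return PhantomSpec(
        style=style,
        matrix=matrix,
        spacing=spacing,
        tumor_radius_frac=float(rng.uniform(0.25, 0.6)),
        necrosis_frac=necrosis,
        ventriculomegaly=bool(rng.random() < 0.5),
        midline_shift_mm=float(rng.uniform(0.0, 0.6)) if rng.random() < 0.4 else 0.0,
        enhancement=enhancement,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def easy_specs(n: int, seed: int, matrix=(64, 64, 64),
               spacing=(0.5, 0.5, 0.5), base_snr: float = 15.0) -> list[PhantomSpec]:
    """Desk-scale training specs: large, well-enhanced tumors on an
    isotropic 64^3 grid, no confounding signs. Used for the
    parameter-recovery checks and the demo pipeline."""
    rng = np.random.default_rng(seed)
    return [
        PhantomSpec(
            style="leuven_like", matrix=matrix, spacing=spacing,
            tumor_radius_frac=float(rng.uniform(0.45, 0.6)),
            necrosis_frac=0.0, ventriculomegaly=False, midline_shift_mm=0.0,
            enhancement="well", base_snr=base_snr,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for _ in range(n)
    ]


MANIFEST_FIELDS = ["case_id", "style", "matrix", "spacing", "tumor_radius_frac",
                   "necrosis_frac", "ventriculomegaly", "midline_shift_mm",
                   "enhancement", "base_snr", "seed"]


def generate_dataset(n: int, style_mix: float, seed: int,
                     out_dir: str | Path, matrix=None, spacing=None) -> list[Path]:
    """Write ``n`` phantom cases in the standard case layout plus a
    ``manifest.csv`` recording every spec. ``style_mix`` is the proportion
    of leuven_like cases; deterministic given ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= style_mix <= 1.0):
        raise ValueError("style_mix must be in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_leuven = int(round(style_mix * n))
    styles = ["leuven_like"] * n_leuven + ["tcia_like"] * (n - n_leuven)
    paths: list[Path] = []
    rows: list[dict] = []
    for i, style in enumerate(styles):
        spec = sample_spec(style, rng, matrix=matrix, spacing=spacing)
        case = generate_phantom(spec)
        case.record.case_id = f"case{i:03d}"
        case_dir = out_dir / case.record.case_id
        save_case(case.record, case_dir)
        paths.append(case_dir)
        row = dataclasses.asdict(spec)
        row["case_id"] = case.record.case_id
        row["matrix"] = "x".join(map(str, spec.matrix))
        row["spacing"] = "x".join(f"{s:g}" for s in spec.spacing)
        rows.append({k: row[k] for k in MANIFEST_FIELDS})
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_FIELDS)
        writer.writeheader()
        writer.writerows(rows)
    return paths
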
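"""Digital rat-head phantoms for microbeam radiation therapy (MRT) dose studies.

A phantom is a 3D lattice of material labels (air / water-equivalent soft
tissue / compact bone) on an isotropic macrovoxel grid.  The beam travels
along axis 0 (depth), entering at index 0.  The canonical prediction volume
is 96 x 16 x 16 voxels of 0.5 mm (48 x 8 x 8 mm^3), centred on the brain.

This module provides HU-threshold segmentation of CT volumes, water-bolus
addition on the beam-entry surface, material-to-density conversion, and a
parametric synthetic head generator (ellipsoidal skull shell, brain, tumor,
optional air cavity and spine-like bone column) used in place of subject CTs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

AIR, WATER, BONE = 0, 1, 2
MATERIAL_NAMES = {AIR: "air", WATER: "water", BONE: "bone"}

#: Mass densities in g/cm^3 for the three reference materials
#: (dry air, liquid water, compact bone).
DEFAULT_DENSITIES = {AIR: 0.0012, WATER: 1.000, BONE: 1.85}

#: Default HU cut points for the air/water/bone split of a CT volume.
DEFAULT_AIR_HU = -300.0
DEFAULT_BONE_HU = 300.0

CANONICAL_SHAPE = (96, 16, 16)
CANONICAL_VOXEL_MM = 0.5


@dataclass
class MaterialGrid:
    """3D material-label lattice with voxel geometry.

    labels    : int array (D, H, W), values in {0=air, 1=water, 2=bone}
    voxel_size: isotropic voxel edge in mm
    beam_axis : depth axis index (always 0; beam travels toward increasing index)
    origin_mm : position of the (0,0,0) voxel corner in mm
    """

    labels: np.ndarray
    voxel_size: float = CANONICAL_VOXEL_MM
    beam_axis: int = 0
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or min(self.labels.shape) < 1:
            raise ValueError("labels must be a non-empty 3D lattice")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if not np.isin(self.labels, (AIR, WATER, BONE)).all():
            raise ValueError("labels must be in {0=air, 1=water, 2=bone}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.beam_axis != 0:
            raise ValueError("beam axis is fixed to axis 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def copy(self) -> "MaterialGrid":
        return replace(self, labels=self.labels.copy())


@dataclass
class TumorMask:
    """Boolean tumor mask aligned with a MaterialGrid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def validate_against(self, grid: MaterialGrid) -> None:
        if self.mask.shape != grid.shape:
            raise ValueError("tumor mask shape does not match grid")
        if not (grid.labels[self.mask] == WATER).all():
            raise ValueError("tumor voxels must be soft tissue (water)")


@dataclass
class DensityGrid:
    """Per-voxel mass density (g/cm^3) on the same lattice as a MaterialGrid."""

    density: np.ndarray
    voxel_size: float = CANONICAL_VOXEL_MM

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.ndim != 3:
            raise ValueError("density must be 3D")
        if not (self.density > 0).all():
            raise ValueError("density must be strictly positive")


def segment_hu(
    hu_volume: np.ndarray,
    air_threshold: float = DEFAULT_AIR_HU,
    bone_threshold: float = DEFAULT_BONE_HU,
    voxel_size: float = CANONICAL_VOXEL_MM,
) -> MaterialGrid:
    """Threshold a Hounsfield-unit volume into air / water / bone labels.

    Voxels with HU below ``air_threshold`` become air, above
    ``bone_threshold`` bone, everything in between water-equivalent tissue.
    """
    hu = np.asarray(hu_volume, dtype=float)
    if hu.ndim != 3:
        raise ValueError("HU volume must be 3D")
    if not np.isfinite(hu).all():
        raise ValueError("HU volume contains non-finite values")
    if not air_threshold < bone_threshold:
        raise ValueError("air_threshold must be strictly below bone_threshold")
    labels = np.full(hu.shape, WATER, dtype=np.int8)
    labels[hu < air_threshold] = AIR
    labels[hu > bone_threshold] = BONE
    return MaterialGrid(labels=labels, voxel_size=voxel_size)


def labels_to_hu_midpoints(
    grid: MaterialGrid,
    air_threshold: float = DEFAULT_AIR_HU,
    bone_threshold: float = DEFAULT_BONE_HU,
    span: float = 700.0,
) -> np.ndarray:
    """Map labels back to representative HU values (class mid-points).

    Round-tripping through :func:`segment_hu` with the same thresholds
    recovers the labels exactly; useful for testing and for exporting
    synthetic phantoms as pseudo-CT volumes.
    """
    hu = np.empty(grid.shape, dtype=float)
    hu[grid.labels == AIR] = air_threshold - span
    hu[grid.labels == WATER] = 0.5 * (air_threshold + bone_threshold)
    hu[grid.labels == BONE] = bone_threshold + span
    return hu


def add_bolus(grid: MaterialGrid, thickness_mm: float) -> MaterialGrid:
    """Prepend a water bolus layer on the beam-entry face (axis 0, index 0).

    The thickness is rounded *up* to a whole number of voxel layers when it
    is not an integer multiple of the voxel size (a warning is logged).
    Returns a new grid extended along the depth axis; the original voxels
    are unchanged.
    """
    if thickness_mm < 0:
        raise ValueError("bolus thickness must be non-negative")
    ratio = thickness_mm / grid.voxel_size
    n_layers = int(round(ratio))
    if abs(ratio - n_layers) > 1e-9:
        n_layers = int(np.ceil(ratio - 1e-9))
        logger.warning(
            "bolus thickness %.3f mm is not a multiple of the %.3f mm voxel; "
            "rounded up to %d layers",
            thickness_mm,
            grid.voxel_size,
            n_layers,
        )
    if n_layers == 0:
        return grid.copy()
    bolus = np.full((n_layers,) + grid.shape[1:], WATER, dtype=grid.labels.dtype)
    labels = np.concatenate([bolus, grid.labels], axis=0)
    ox, oy, oz = grid.origin_mm
    return MaterialGrid(
        labels=labels,
        voxel_size=grid.voxel_size,
        origin_mm=(ox - n_layers * grid.voxel_size, oy, oz),
    )


def crop_to_depth(grid: MaterialGrid, mask: TumorMask | None, depth: int) -> tuple[MaterialGrid, TumorMask | None]:
    """Crop to the first ``depth`` layers along the beam axis.

    Used to restore the canonical 96-layer prediction volume after bolus
    addition, so the model input shape is constant.
    """
    if grid.shape[0] < depth:
        raise ValueError(f"grid has only {grid.shape[0]} depth layers, need {depth}")
    cropped = MaterialGrid(
        labels=grid.labels[:depth].copy(),
        voxel_size=grid.voxel_size,
        origin_mm=grid.origin_mm,
    )
    cmask = None
    if mask is not None:
        cmask = TumorMask(mask.mask[:depth].copy())
    return cropped, cmask


def materials_to_density(
    grid: MaterialGrid, density_table: dict[int, float] | None = None
) -> DensityGrid:
    """Convert material labels to a mass-density lattice by table lookup."""
    table = DEFAULT_DENSITIES if density_table is None else density_table
    present = np.unique(grid.labels)
    missing = [int(m) for m in present if int(m) not in table]
    if missing:
        names = ", ".join(MATERIAL_NAMES.get(m, str(m)) for m in missing)
        raise KeyError(f"density table lacks entries for material(s): {names}")
    lut = np.zeros(max(table) + 1, dtype=float)
    for mat, rho in table.items():
        lut[mat] = rho
    return DensityGrid(density=lut[grid.labels], voxel_size=grid.voxel_size)


@dataclass
class SyntheticHeadParams:
    """Geometry ranges (mm) for the parametric synthetic rat-head generator.

    The head is modelled in the canonical beam-aligned frame: air above the
    scalp, an ellipsoidal compact-bone skull shell whose crown faces the
    beam, water-equivalent brain inside, an ellipsoidal tumor inside the
    brain, and optionally a small air cavity (auditory-canal analogue) and a
    deep bone column (spine analogue).  All ranges are sampled uniformly.
    """

    shape: tuple[int, int, int] = CANONICAL_SHAPE
    voxel_mm: float = CANONICAL_VOXEL_MM
    # outer skull ellipsoid semi-axes (depth, lateral, lateral), mm
    skull_semi_depth: tuple[float, float] = (14.0, 18.0)
    skull_semi_lat: tuple[float, float] = (9.0, 13.0)
    # depth of the skull centre below the entry face, mm
    skull_center_depth: tuple[float, float] = (20.0, 26.0)
    # lateral offset of the skull centre from the window centre, mm
    skull_center_lat_offset: tuple[float, float] = (-1.0, 1.0)
    skull_thickness: tuple[float, float] = (0.5, 1.5)
    # tumor ellipsoid semi-axes, mm
    tumor_semi: tuple[float, float] = (1.5, 3.0)
    # tumor centre offset from the brain centre, mm (each axis)
    tumor_offset: tuple[float, float] = (-2.0, 2.0)
    air_cavity_prob: float = 0.5
    air_cavity_semi: tuple[float, float] = (0.8, 1.6)
    spine_prob: float = 0.5
    spine_radius: tuple[float, float] = (1.0, 2.0)
    # acceptable material fractions used as generator self-checks
    bone_fraction_bounds: tuple[float, float] = (0.005, 0.45)


def _ellipsoid(coords, center, semi):
    """Boolean ellipsoid membership on (3, D, H, W) voxel-centre coords."""
    acc = np.zeros(coords.shape[1:], dtype=float)
    for c, mu, a in zip(coords, center, semi):
        acc += ((c - mu) / a) ** 2
    return acc <= 1.0


def generate_synthetic_head(
    seed: int, params: SyntheticHeadParams | None = None
) -> tuple[MaterialGrid, TumorMask]:
    """Generate one synthetic rat-head phantom and tumor mask.

    Deterministic for a fixed seed.  Raises if the sampled tumor cannot fit
    inside the brain compartment.
    """
    p = params or SyntheticHeadParams()
    rng = np.random.default_rng(seed)
    dz = p.voxel_mm
    shape = tuple(p.shape)
    # voxel-centre coordinates in mm
    axes = [(np.arange(n) + 0.5) * dz for n in shape]
    coords = np.stack(np.meshgrid(*axes, indexing="ij"))

    lat_mid = [shape[1] * dz / 2.0, shape[2] * dz / 2.0]
    sk_center = np.array(
        [
            rng.uniform(*p.skull_center_depth),
            lat_mid[0] + rng.uniform(*p.skull_center_lat_offset),
            lat_mid[1] + rng.uniform(*p.skull_center_lat_offset),
        ]
    )
    sk_semi = np.array(
        [
            rng.uniform(*p.skull_semi_depth),
            rng.uniform(*p.skull_semi_lat),
            rng.uniform(*p.skull_semi_lat),
        ]
    )
    thickness = rng.uniform(*p.skull_thickness)

    labels = np.full(shape, AIR, dtype=np.int8)
    outer = _ellipsoid(coords, sk_center, sk_semi)
    inner = _ellipsoid(coords, sk_center, np.maximum(sk_semi - thickness, 1e-6))
    if thickness > 0:
        labels[outer] = BONE
    labels[inner] = WATER

    # spine-like bone column entering from the deep end, off-centre
    if rng.uniform() < p.spine_prob:
        r = rng.uniform(*p.spine_radius)
        cy = lat_mid[0] + rng.uniform(-2.0, 2.0)
        cz = lat_mid[1] + rng.uniform(-2.0, 2.0)
        start = sk_center[0] + sk_semi[0] * rng.uniform(0.75, 0.95)
        col = ((coords[1] - cy) ** 2 + (coords[2] - cz) ** 2 <= r**2) & (
            coords[0] >= start
        )
        labels[col & ~inner] = BONE

    # brain centre: centroid of interior water voxels
    brain_idx = np.argwhere(labels == WATER)
    if brain_idx.size == 0:
        raise ValueError("degenerate geometry: no brain compartment")
    brain_center = (brain_idx.mean(axis=0) + 0.5) * dz

    # tumor (with a half-voxel margin) must fit inside the inner ellipsoid;
    # redraw within the configured ranges, reject only if no draw can fit
    margin = dz / 2.0
    tumor_center = tumor_semi = None
    for _ in range(50):
        semi = rng.uniform(*p.tumor_semi, size=3)
        center = brain_center + rng.uniform(*p.tumor_offset, size=3)
        inner_semi = np.maximum(sk_semi - thickness, 0)
        if (inner_semi <= semi + margin).any():
            continue
        rel = (center - sk_center) / (inner_semi - semi - margin)
        if (rel**2).sum() <= 1.0:
            tumor_center, tumor_semi = center, semi
            break
    if tumor_center is None:
        raise ValueError("tumor parameters do not fit inside the brain")
    tumor = _ellipsoid(coords, tumor_center, tumor_semi) & inner

    # optional air cavity (auditory-canal analogue), kept clear of the tumor
    if rng.uniform() < p.air_cavity_prob:
        cav_semi = rng.uniform(*p.air_cavity_semi, size=3)
        for _ in range(20):
            offset = rng.uniform(-0.5, 0.5, size=3) * (sk_semi - thickness)
            offset[0] = abs(offset[0])  # below the brain centre, away from crown
            cav_center = sk_center + offset
            cav = _ellipsoid(coords, cav_center, cav_semi) & inner
            if not (cav & tumor).any():
                labels[cav] = AIR
                break

    tumor &= labels == WATER
    if not tumor.any():
        raise ValueError("tumor mask is empty after voxelization")

    grid = MaterialGrid(labels=labels, voxel_size=dz)
    mask = TumorMask(tumor)
    mask.validate_against(grid)

    bone_frac = float((labels == BONE).mean())
    lo, hi = p.bone_fraction_bounds
    if thickness > 0 and not (lo <= bone_frac <= hi):
        warnings.warn(
            f"bone fraction {bone_frac:.3f} outside configured bounds [{lo}, {hi}]",
            stacklevel=2,
        )
    return grid, mask


def load_nifti_hu(path: str) -> np.ndarray:
    """Read a NIfTI volume and return its data as Hounsfield units."""
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover
        raise ImportError("nibabel is required for NIfTI input (pip install mrtdose[imaging])") from exc
    img = nib.load(path)
    return np.asarray(img.get_fdata(), dtype=float)


def load_dicom_series_hu(paths: list[str]) -> np.ndarray:
    """Read a DICOM CT series (one file per slice) into a HU volume.

    Slices are sorted by ImagePositionPatient along the slice axis and
    rescaled with RescaleSlope/Intercept.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise ImportError("pydicom is required for DICOM input (pip install mrtdose[imaging])") from exc
    slices = [pydicom.dcmread(p) for p in paths]
    slices.sort(key=lambda s: float(getattr(s, "ImagePositionPatient", [0, 0, 0])[2]))
    vol = []
    for s in slices:
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        vol.append(s.pixel_array.astype(float) * slope + intercept)
    return np.stack(vol, axis=0)
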
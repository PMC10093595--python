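"""Phantom augmentation: random rigid-ish transforms before dose simulation.

Each augmented sample is the base phantom translated in the plane
perpendicular to the beam (up to +-5 mm), rotated about the brain centre
(up to +-10 degrees per axis) and scaled isotropically (voxel-size factor
0.8-1.2), then resampled with nearest-neighbour interpolation back onto the
fixed 96 x 16 x 16 macrovoxel frame.  Voxels mapped from outside the source
grid become air.  The tumor mask is carried through the identical mapping,
so a tumor voxel always remains soft tissue.

Conventions (fixed and tested): intrinsic X->Y->Z rotation about the brain
centroid, scaling about the same centre, translation applied last.  A scale
factor s enlarges the voxels, i.e. the anatomy occupies ~1/s^3 as many
voxels.  Draws whose transformed tumor would leave the lateral field are
rejected and redrawn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .phantom import AIR, WATER, MaterialGrid, TumorMask

DEFAULT_TRANSLATION_MM = 5.0
DEFAULT_ROTATION_DEG = 10.0
DEFAULT_SCALE_RANGE = (0.8, 1.2)


@dataclass
class TransformRanges:
    """Closed sampling ranges for one augmentation draw."""

    translation_mm: float = DEFAULT_TRANSLATION_MM
    rotation_deg: float = DEFAULT_ROTATION_DEG
    scale: tuple[float, float] = DEFAULT_SCALE_RANGE

    def validate(self) -> None:
        if self.translation_mm < 0 or self.rotation_deg < 0:
            raise ValueError("range half-widths must be non-negative")
        if not self.scale[0] <= self.scale[1]:
            raise ValueError("scale range must satisfy lo <= hi")
        if self.scale[0] <= 0:
            raise ValueError("scale must be positive")


@dataclass
class TransformSpec:
    """One augmentation draw.

    translation_mm: (u, v) shift in the two lateral axes (perpendicular to
    the beam); rotation_deg: rotations about the three grid axes, applied
    intrinsically X->Y->Z about the brain centre; scale: isotropic
    voxel-size factor; seed: the draw's seed (provenance).
    """

    translation_mm: tuple[float, float]
    rotation_deg: tuple[float, float, float]
    scale: float
    seed: int

    def is_identity(self) -> bool:
        return (
            all(t == 0 for t in self.translation_mm)
            and all(r == 0 for r in self.rotation_deg)
            and self.scale == 1.0
        )

    @classmethod
    def identity(cls, seed: int = 0) -> "TransformSpec":
        return cls((0.0, 0.0), (0.0, 0.0, 0.0), 1.0, seed)


def sample_transform(seed: int, ranges: TransformRanges | None = None) -> TransformSpec:
    """Draw one TransformSpec uniformly within the configured ranges."""
    r = ranges or TransformRanges()
    r.validate()
    rng = np.random.default_rng(seed)
    t = rng.uniform(-r.translation_mm, r.translation_mm, size=2)
    rot = rng.uniform(-r.rotation_deg, r.rotation_deg, size=3)
    s = rng.uniform(r.scale[0], r.scale[1])
    return TransformSpec(tuple(t), tuple(rot), float(s), seed)


def _rotation_matrix(rotation_deg) -> np.ndarray:
    """Intrinsic X->Y->Z rotation, axes = grid axes (0=depth, 1, 2)."""
    ax, ay, az = np.deg2rad(rotation_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rx @ ry @ rz


def brain_center_voxels(grid: MaterialGrid, mask: TumorMask | None = None) -> np.ndarray:
    """Rotation centre: centroid of the soft-tissue (brain) compartment,
    falling back to the tumor centroid, in voxel coordinates."""
    idx = np.argwhere(grid.labels == WATER)
    if idx.size == 0 and mask is not None and mask.mask.any():
        idx = np.argwhere(mask.mask)
    if idx.size == 0:
        return (np.asarray(grid.shape, dtype=float) - 1) / 2.0
    return idx.mean(axis=0)


def _inverse_affine(grid: MaterialGrid, t: TransformSpec, center_vox: np.ndarray):
    """Matrix/offset mapping output voxel coords -> source voxel coords.

    Forward object map (voxel units): y = c + R (x - c) / s + d, where d is
    the lateral translation in voxels.  The inverse used for resampling is
    x = c + s R^T (y - c - d).
    """
    if t.scale <= 0:
        raise ValueError("scale must be positive")
    rot = _rotation_matrix(t.rotation_deg)
    disp = np.array([0.0, t.translation_mm[0], t.translation_mm[1]]) / grid.voxel_size
    matrix = t.scale * rot.T
    offset = center_vox - matrix @ (center_vox + disp)
    return matrix, offset


def apply_transform(
    grid: MaterialGrid, mask: TumorMask | None, t: TransformSpec,
    center_vox: np.ndarray | None = None,
) -> tuple[MaterialGrid, TumorMask | None]:
    """Resample a phantom (and its tumor mask) under one TransformSpec.

    Nearest-neighbour interpolation keeps the three-material vocabulary;
    out-of-domain voxels become air.  Identity transforms return exact
    copies.  The rotation/scaling centre defaults to the brain centroid;
    pass ``center_vox`` to pin it (e.g. for exact round trips).
    """
    if t.is_identity():
        return grid.copy(), TumorMask(mask.mask.copy()) if mask is not None else None
    center = brain_center_voxels(grid, mask) if center_vox is None else np.asarray(center_vox, float)
    matrix, offset = _inverse_affine(grid, t, center)
    labels = ndimage.affine_transform(
        grid.labels, matrix, offset=offset, order=0, mode="constant", cval=AIR,
        output=grid.labels.dtype,
    )
    new_grid = MaterialGrid(labels=labels, voxel_size=grid.voxel_size, origin_mm=grid.origin_mm)
    new_mask = None
    if mask is not None:
        m = ndimage.affine_transform(
            mask.mask.astype(np.uint8), matrix, offset=offset, order=0,
            mode="constant", cval=0,
        )
        new_mask = TumorMask(m.astype(bool))
    return new_grid, new_mask


def _tumor_stays_in_field(
    grid: MaterialGrid, mask: TumorMask, t: TransformSpec, margin_vox: float = 0.5
) -> bool:
    """Cheap admissibility check: map the tumor bounding-box corners through
    the forward transform and require them to stay inside the lateral field.
    (The beam field covers the whole lateral window, so 'the beam still
    targets the tumor' reduces to the tumor staying inside the frame.)"""
    idx = np.argwhere(mask.mask)
    if idx.size == 0:
        return False
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    corners = np.array([[a, b, c] for a in (lo[0], hi[0]) for b in (lo[1], hi[1]) for c in (lo[2], hi[2])], dtype=float)
    center = brain_center_voxels(grid, mask)
    rot = _rotation_matrix(t.rotation_deg)
    disp = np.array([0.0, t.translation_mm[0], t.translation_mm[1]]) / grid.voxel_size
    mapped = center + (corners - center) @ rot.T / t.scale + disp
    shape = np.asarray(grid.shape, dtype=float)
    ok = (mapped >= -margin_vox).all() and (mapped <= shape - 1 + margin_vox).all()
    return bool(ok)


@dataclass
class CohortSample:
    """Provenance record for one augmented sample."""

    sample_id: str
    base_id: str
    partition: str
    transform: TransformSpec
    seed: int


def build_augmented_cohort(
    base_phantoms: dict[str, tuple[MaterialGrid, TumorMask]],
    n_samples: dict[str, int],
    split: dict[str, str],
    seed: int,
    ranges: TransformRanges | None = None,
    max_redraws: int = 100,
) -> list[CohortSample]:
    """Build the augmentation manifest for a train/val/test cohort.

    ``split`` assigns each base phantom id to exactly one partition;
    every augmented sample descends from a base phantom of its own
    partition (no subject leakage).  Per-sample seeds are spawned from the
    master seed with ``numpy.random.SeedSequence`` (counter-based) and
    recorded in the manifest.  Transform draws whose tumor would leave the
    lateral field are redrawn with a fresh child seed.
    """
    ranges = ranges or TransformRanges()
    if not isinstance(split, dict):
        pairs = list(split)
        seen: dict[str, str] = {}
        for pid, part in pairs:
            if pid in seen and seen[pid] != part:
                raise ValueError(f"base phantom {pid!r} assigned to two partitions")
            seen[pid] = part
        split = seen
    partitions = sorted(set(split.values()))
    for pid in base_phantoms:
        if pid not in split:
            raise ValueError(f"base phantom {pid!r} has no partition assignment")
    for part in n_samples:
        if part not in partitions:
            raise ValueError(f"no base phantom assigned to partition {part!r}")
    by_part: dict[str, list[str]] = {p: [] for p in partitions}
    for pid, part in split.items():
        if pid not in base_phantoms:
            raise ValueError(f"split references unknown phantom {pid!r}")
        by_part[part].append(pid)
    for part in by_part:
        by_part[part].sort()

    root = np.random.SeedSequence(seed)
    cohort: list[CohortSample] = []
    for part in sorted(n_samples):
        bases = by_part[part]
        for k in range(n_samples[part]):
            base_id = bases[k % len(bases)]
            grid, mask = base_phantoms[base_id]
            spec = None
            for _ in range(max_redraws):
                child = root.spawn(1)[0]
                draw_seed = int(child.generate_state(1)[0] % (2**31))
                candidate = sample_transform(draw_seed, ranges)
                if _tumor_stays_in_field(grid, mask, candidate):
                    spec = candidate
                    break
            if spec is None:
                raise RuntimeError(
                    f"could not draw an admissible transform for base {base_id!r}"
                )
            cohort.append(
                CohortSample(
                    sample_id=f"{part}-{k:05d}",
                    base_id=base_id,
                    partition=part,
                    transform=spec,
                    seed=spec.seed,
                )
            )
    return cohort


def cohort_to_json(cohort: list[CohortSample], path: str) -> None:
    """Serialize a cohort manifest to JSON."""
    records = []
    for s in cohort:
        rec = asdict(s)
        rec["transform"]["translation_mm"] = list(s.transform.translation_mm)
        rec["transform"]["rotation_deg"] = list(s.transform.rotation_deg)
        records.append(rec)
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1, sort_keys=True)


def cohort_from_json(path: str) -> list[CohortSample]:
    with open(path) as fh:
        records = json.load(fh)
    cohort = []
    for rec in records:
        tr = rec["transform"]
        cohort.append(
            CohortSample(
                sample_id=rec["sample_id"],
                base_id=rec["base_id"],
                partition=rec["partition"],
                transform=TransformSpec(
                    tuple(tr["translation_mm"]),
                    tuple(tr["rotation_deg"]),
                    tr["scale"],
                    tr["seed"],
                ),
                seed=rec["seed"],
            )
        )
    return cohort
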
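"""Noise-aware dose-comparison statistics.

Implements the performance measures used to judge a machine-learned dose
map against Monte-Carlo-style reference data:

* voxelwise MAE over a target region;
* the 1-sigma consistency fraction: with an unbiased prediction of noisy
  reference data, ~68 % of voxels are expected to agree within one standard
  error of the reference mean — a smaller fraction hints at a systematic
  deviation, a larger one at overfitting to the noise;
* relative dose-difference maps dDrel = (D_ML - D_MC) / D_ML with coverage
  fractions at strict thresholds (3 % satisfactory, 10 % reporting bin)
  over the full volume, tissue-only and tumor masks;
* peak-to-valley dose ratio (PVDR) maps and their relative deviation
  (PVDR_ML - PVDR_MC) / PVDR_ML;
* the prescription-dose consistency: irradiation time is fixed by scaling
  the minimum valley dose over the tumor to a prescription dose D*, so the
  delivered-dose deviation between two plans reduces to
  dD = (min_MC / min_ML - 1) * 100 %, independent of D*.

Voxels where a statistic is undefined (non-positive denominator, zero SE)
are excluded from coverage denominators and counted explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dosesim import DoseGrid
from .phantom import WATER, MaterialGrid

#: dDrel magnitudes (percent) used for discretized map reporting.
REL_DIFF_BINS_PCT = (1.0, 3.0, 5.0, 10.0)


def _values(grid) -> np.ndarray:
    return grid.values if isinstance(grid, DoseGrid) else np.asarray(grid, dtype=float)


def mae(pred, ref, region: np.ndarray | None = None) -> float:
    """Mean absolute voxelwise difference over a target region."""
    p, r = _values(pred), _values(ref)
    if p.shape != r.shape:
        raise ValueError("shape mismatch")
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if region.shape != p.shape:
            raise ValueError("region shape mismatch")
        if not region.any():
            raise ValueError("empty target region")
        p, r = p[region], r[region]
    if p.size == 0:
        raise ValueError("empty target region")
    return float(np.abs(p - r).mean())


def frac_within_sigma(pred, mc_mean, mc_se, k: float = 1.0) -> float:
    """Fraction of voxels with |pred - mean| <= k * SE.

    Voxels with zero (or negative) SE carry no noise estimate and are
    excluded from the denominator.
    """
    p, m, s = _values(pred), _values(mc_mean), np.asarray(mc_se, dtype=float)
    if not (p.shape == m.shape == s.shape):
        raise ValueError("shape mismatch")
    valid = s > 0
    if not valid.any():
        raise ValueError("all voxels have zero standard error")
    agree = np.abs(p[valid] - m[valid]) <= k * s[valid]
    return float(agree.mean())


@dataclass
class DiffMap:
    """Voxelwise relative dose difference (D_ML - D_MC) / D_ML in percent."""

    delta_rel_pct: np.ndarray
    defined: np.ndarray
    n_undefined: int

    def discretized(self, bins_pct=REL_DIFF_BINS_PCT) -> np.ndarray:
        """Map |dDrel| to discrete magnitude steps (index into bins; the
        last bin collects everything above the largest edge).  Undefined
        voxels are -1."""
        out = np.full(self.delta_rel_pct.shape, -1, dtype=int)
        mag = np.abs(self.delta_rel_pct)
        out[self.defined] = np.searchsorted(np.asarray(bins_pct), mag[self.defined], side="right")
        return out


def rel_dose_diff(pred, ref) -> DiffMap:
    """dDrel map with the ML prediction as the denominator."""
    p, r = _values(pred), _values(ref)
    if p.shape != r.shape:
        raise ValueError("shape mismatch")
    defined = p > 0
    delta = np.full(p.shape, np.nan)
    delta[defined] = 100.0 * (p[defined] - r[defined]) / p[defined]
    return DiffMap(delta_rel_pct=delta, defined=defined, n_undefined=int((~defined).sum()))


def coverage(diffmap: DiffMap, threshold_pct: float, mask: np.ndarray | None = None) -> float:
    """Fraction of (defined, masked) voxels with |dDrel| strictly below the
    threshold."""
    sel = diffmap.defined.copy()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != sel.shape:
            raise ValueError("mask shape mismatch")
        if not mask.any():
            raise ValueError("empty mask")
        sel &= mask
    if not sel.any():
        raise ValueError("no defined voxels under the mask")
    return float((np.abs(diffmap.delta_rel_pct[sel]) < threshold_pct).mean())


def tissue_mask(grid: MaterialGrid) -> np.ndarray:
    """Soft tissue only: water voxels, excluding bone and air."""
    return grid.labels == WATER


@dataclass
class PVDRMap:
    """Peak-to-valley dose ratio per macrovoxel."""

    pvdr: np.ndarray
    defined: np.ndarray

    @property
    def n_undefined(self) -> int:
        return int((~self.defined).sum())


def pvdr_map(peak, valley) -> PVDRMap:
    """Elementwise peak/valley ratio; voxels with zero valley are flagged."""
    p, v = _values(peak), _values(valley)
    if p.shape != v.shape:
        raise ValueError("shape mismatch")
    defined = v > 0
    ratio = np.full(p.shape, np.nan)
    ratio[defined] = p[defined] / v[defined]
    return PVDRMap(pvdr=ratio, defined=defined)


def pvdr_diff(ml: PVDRMap, mc: PVDRMap) -> DiffMap:
    """(PVDR_ML - PVDR_MC) / PVDR_ML in percent, ML denominator."""
    defined = ml.defined & mc.defined & (ml.pvdr > 0)
    delta = np.full(ml.pvdr.shape, np.nan)
    delta[defined] = 100.0 * (ml.pvdr[defined] - mc.pvdr[defined]) / ml.pvdr[defined]
    return DiffMap(delta_rel_pct=delta, defined=defined, n_undefined=int((~defined).sum()))


@dataclass
class PrescriptionSpec:
    """Prescription valley dose D* (Gy) to be reached as a minimum over the
    whole tumor; D* cancels in plan comparisons but is kept for reporting."""

    d_star: float
    tumor_mask: np.ndarray = None

    def __post_init__(self) -> None:
        if self.d_star <= 0:
            raise ValueError("prescription dose must be positive")
        if self.tumor_mask is not None:
            self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
            if not self.tumor_mask.any():
                raise ValueError("tumor mask is empty")


def prescription_delta(ml_valley, mc_valley, rx: PrescriptionSpec) -> float:
    """Delivered-dose deviation (percent) of an ML-planned irradiation.

    Each plan scales its valley dose so the tumor minimum reaches D*:
    scale_X = D* / min_tumor(valley_X).  The delivered-dose ratio of the
    two plans is scale_ML / scale_MC = min_MC / min_ML, so
    dD = (min_MC / min_ML - 1) * 100, independent of D*.  Positive dD
    means the ML-planned irradiation delivers more dose than the MC truth
    requires.
    """
    if rx.tumor_mask is None:
        raise ValueError("prescription requires a tumor mask")
    ml, mc = _values(ml_valley), _values(mc_valley)
    if ml.shape != mc.shape or ml.shape != rx.tumor_mask.shape:
        raise ValueError("shape mismatch")
    min_ml = float(ml[rx.tumor_mask].min())
    min_mc = float(mc[rx.tumor_mask].min())
    if min_ml <= 0 or min_mc <= 0:
        raise ValueError("minimum valley dose in the tumor must be positive")
    return (min_mc / min_ml - 1.0) * 100.0


def depth_profile(grid, lateral_index: tuple[int, int]) -> np.ndarray:
    """The dose-vs-depth lattice column at one lateral position."""
    v = _values(grid)
    j, k = lateral_index
    if not (0 <= j < v.shape[1] and 0 <= k < v.shape[2]):
        raise IndexError(f"lateral index {lateral_index} out of range for {v.shape}")
    return v[:, j, k].copy()


@dataclass
class EvalReport:
    """All per-sample comparison statistics for one prediction/reference pair."""

    sample_id: str
    channel: str
    mae: float
    frac_within_1sigma: float | None
    coverage_3pct: dict[str, float] = field(default_factory=dict)
    coverage_10pct: dict[str, float] = field(default_factory=dict)
    pvdr_coverage_5pct: float | None = None
    prescription_delta_pct: float | None = None
    n_undefined: int = 0
    denominators: dict[str, int] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "sample_id": self.sample_id,
            "channel": self.channel,
            "mae": self.mae,
            "frac_within_1sigma": self.frac_within_1sigma,
            "pvdr_coverage_5pct": self.pvdr_coverage_5pct,
            "prescription_delta_pct": self.prescription_delta_pct,
            "n_undefined": self.n_undefined,
        }
        for region, val in self.coverage_3pct.items():
            row[f"coverage_3pct_{region}"] = val
        for region, val in self.coverage_10pct.items():
            row[f"coverage_10pct_{region}"] = val
        return row


def evaluate_sample(
    sample_id: str,
    channel: str,
    pred,
    ref,
    ref_se: np.ndarray | None = None,
    materials: MaterialGrid | None = None,
    tumor: np.ndarray | None = None,
) -> EvalReport:
    """Compute the full statistics bundle for one prediction/reference pair.

    Coverage is reported for the full volume and, when the material grid /
    tumor mask are given, for tissue-only and tumor regions.
    """
    diff = rel_dose_diff(pred, ref)
    regions: dict[str, np.ndarray | None] = {"full": None}
    denominators = {"full": int(diff.defined.sum())}
    if materials is not None:
        tm = tissue_mask(materials)
        regions["tissue"] = tm
        denominators["tissue"] = int((diff.defined & tm).sum())
    if tumor is not None:
        tumor = np.asarray(tumor, dtype=bool)
        regions["tumor"] = tumor
        denominators["tumor"] = int((diff.defined & tumor).sum())

    report = EvalReport(
        sample_id=sample_id,
        channel=channel,
        mae=mae(pred, ref),
        frac_within_1sigma=(
            frac_within_sigma(pred, ref, ref_se) if ref_se is not None else None
        ),
        n_undefined=diff.n_undefined,
        denominators=denominators,
    )
    for name, region in regions.items():
        report.coverage_3pct[name] = coverage(diff, 3.0, region)
        report.coverage_10pct[name] = coverage(diff, 10.0, region)
    return report


def report_table(reports: list[EvalReport]):
    """Aggregate per-sample reports into a pandas DataFrame (one row each)."""
    import pandas as pd

    if not reports:
        raise ValueError("no reports to tabulate")
    return pd.DataFrame([r.to_row() for r in reports])
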
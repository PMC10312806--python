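"""Lesion-wise Dice and HD95 with fixed penalties, and cohort analytics.

For one region the case-level scores are

    lesion-wise Dice = (sum_i Dice_i) / (TP + FN + FP)
    lesion-wise HD95 = (sum_i HD95_i) / (TP + FN + FP)

where the sums run over evaluation units and false-positive components:
each true-positive unit contributes its Dice/HD95 against its matched
predicted voxels, each false negative contributes Dice 0 and the fixed
HD95 penalty (374 mm by default), and each false positive contributes 0 to
the Dice numerator and the same penalty to the HD95 numerator. Excluded
(sub-threshold) units contribute nothing. A region with no evaluable units
and no false positives scores Dice 1 / HD95 0 by the vacuous-truth
convention.

HD95 here is the 95th percentile of the *pooled bidirectional* multiset of
surface distances (every boundary voxel of A to its nearest boundary voxel
of B, and vice versa), Euclidean in mm; boundary voxels are foreground
voxels with at least one background 6-neighbor (the array border counts as
background). Conventions differ across toolkits, so this one is stated
explicitly and tested against a brute-force oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import DegenerateCohortError, UndefinedDistanceError
from .label_io import LabelMap, RegionMask, REGIONS, check_comparable, extract_region
from .matching import EvalParams, LesionMatchResult, match_lesions

logger = logging.getLogger(__name__)


@dataclass
class LesionRecord:
    """Per-lesion scoring record used by size-stratified analytics."""

    case_id: str
    region: str
    unit_id: int
    volume_mm3: float
    dice: float
    hd95: float
    detected: bool


@dataclass
class RegionScores:
    """Case-level scores for one evaluation region."""

    region: str
    lesionwise_dice: float
    lesionwise_hd95: float
    legacy_dice: float
    legacy_hd95: float
    tp: int
    fn: int
    fp: int
    n_excluded: int
    lesions: list[LesionRecord] = field(default_factory=list)


@dataclass
class CaseScores:
    """Lesion-wise and legacy scores for one subject, all regions."""

    case_id: str
    regions: dict[str, RegionScores]


@dataclass
class CohortSummary:
    """Cohort-pooled detection statistics and size-stratified curves.

    ``detection_rate`` and ``ppv`` are micro-averages pooled over the
    cohort (sum of TP over sum of TP+FN, resp. TP+FP); ``sensitivity`` is
    the macro-average of per-case TP/(TP+FN), skipping cases with no GT
    lesions in the region.
    """

    detection_rate: dict[str, float]
    sensitivity: dict[str, float]
    ppv: dict[str, float]
    curves: dict[str, dict[str, np.ndarray]]


def dice(a: RegionMask | np.ndarray, b: RegionMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    av = a.voxels if isinstance(a, RegionMask) else np.asarray(a, bool)
    bv = b.voxels if isinstance(b, RegionMask) else np.asarray(b, bool)
    if isinstance(a, RegionMask) and isinstance(b, RegionMask):
        check_comparable(a, b)
    elif av.shape != bv.shape:
        from .errors import ComparisonError

        raise ComparisonError(f"shape mismatch: {av.shape} vs {bv.shape}")
    na, nb = int(av.sum()), int(bv.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(av, bv).sum())
    return 2.0 * inter / (na + nb)


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with >= 1 background 6-neighbor (border = background)."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~eroded


def hd95(
    a: RegionMask | np.ndarray,
    b: RegionMask | np.ndarray,
    spacing: tuple[float, float, float] | None = None,
) -> float:
    """95th percentile of pooled bidirectional surface distances, in mm."""
    av = a.voxels if isinstance(a, RegionMask) else np.asarray(a, bool)
    bv = b.voxels if isinstance(b, RegionMask) else np.asarray(b, bool)
    if spacing is None:
        spacing = a.spacing if isinstance(a, RegionMask) else (1.0, 1.0, 1.0)
    if isinstance(a, RegionMask) and isinstance(b, RegionMask):
        check_comparable(a, b)
    if not av.any() or not bv.any():
        raise UndefinedDistanceError(
            "HD95 is undefined for an empty mask; callers substitute the penalty"
        )
    sp = np.asarray(spacing, float)
    pa = np.argwhere(_boundary_voxels(av)) * sp
    pb = np.argwhere(_boundary_voxels(bv)) * sp
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def lesionwise_scores(
    match: LesionMatchResult,
    params: EvalParams | None = None,
    case_id: str = "",
) -> RegionScores:
    """Aggregate a match result into case-level lesion-wise Dice and HD95.

    Legacy (whole-region) scores are left NaN here; :func:`evaluate_case`
    fills them from the full region masks.
    """
    params = params or match.params
    penalty = params.fp_fn_hd95
    records: list[LesionRecord] = []
    dice_num = 0.0
    hd_num = 0.0
    for unit in match.gt_units:
        if unit.status == "excluded":
            continue
        if unit.status == "TP":
            d = dice(unit.gt_voxels, unit.matched_pred_voxels)
            h = min(
                hd95(unit.gt_voxels, unit.matched_pred_voxels, match.spacing),
                penalty,
            )
            detected = True
        else:  # FN
            d = params.fn_dice
            h = penalty
            detected = False
        dice_num += d
        hd_num += h
        records.append(
            LesionRecord(
                case_id=case_id,
                region=match.region.name,
                unit_id=unit.unit_id,
                volume_mm3=unit.volume_mm3,
                dice=d,
                hd95=h,
                detected=detected,
            )
        )
    hd_num += penalty * match.fp  # each FP charges the full HD95 penalty
    denom = match.tp + match.fn + match.fp
    if denom == 0:
        lw_dice, lw_hd = 1.0, 0.0
    else:
        lw_dice = dice_num / denom
        lw_hd = hd_num / denom
    return RegionScores(
        region=match.region.name,
        lesionwise_dice=lw_dice,
        lesionwise_hd95=lw_hd,
        legacy_dice=float("nan"),
        legacy_hd95=float("nan"),
        tp=match.tp,
        fn=match.fn,
        fp=match.fp,
        n_excluded=match.n_excluded,
        lesions=records,
    )


def evaluate_case(
    gt: LabelMap,
    pred: LabelMap,
    params: EvalParams | None = None,
    case_id: str = "case",
) -> CaseScores:
    """Run region extraction, lesion matching and scoring for ET, TC, WT.

    Also computes legacy whole-region Dice/HD95 on the full region masks
    for comparison with the lesion-wise scores.
    """
    params = params or EvalParams()
    check_comparable(gt, pred)
    out: dict[str, RegionScores] = {}
    for name, spec in REGIONS.items():
        gt_mask = extract_region(gt, spec)
        pred_mask = extract_region(pred, spec)
        match = match_lesions(gt_mask, pred_mask, params)
        scores = lesionwise_scores(match, params, case_id=case_id)
        scores.legacy_dice = dice(gt_mask, pred_mask)
        scores.legacy_hd95 = _legacy_hd95(gt_mask, pred_mask, params)
        out[name] = scores
    return CaseScores(case_id=case_id, regions=out)


def _legacy_hd95(gt_mask: RegionMask, pred_mask: RegionMask, params: EvalParams) -> float:
    gt_empty = not gt_mask.voxels.any()
    pred_empty = not pred_mask.voxels.any()
    if gt_empty and pred_empty:
        return 0.0
    if gt_empty or pred_empty:
        return params.fp_fn_hd95
    return min(hd95(gt_mask, pred_mask, gt_mask.spacing), params.fp_fn_hd95)


def cohort_summary(cases: list[CaseScores]) -> CohortSummary:
    """Pool detection statistics and size-stratified curves over a cohort."""
    if not cases:
        raise DegenerateCohortError("empty cohort")
    detection, sensitivity, ppv = {}, {}, {}
    curves: dict[str, dict[str, np.ndarray]] = {}
    any_evaluable = False
    for name in REGIONS:
        tp = sum(c.regions[name].tp for c in cases)
        fn = sum(c.regions[name].fn for c in cases)
        fp = sum(c.regions[name].fp for c in cases)
        if tp + fn + fp > 0:
            any_evaluable = True
        detection[name] = tp / (tp + fn) if tp + fn > 0 else float("nan")
        per_case = [
            c.regions[name].tp / (c.regions[name].tp + c.regions[name].fn)
            for c in cases
            if c.regions[name].tp + c.regions[name].fn > 0
        ]
        sensitivity[name] = float(np.mean(per_case)) if per_case else float("nan")
        if tp + fp > 0:
            ppv[name] = tp / (tp + fp)
        else:
            warnings.warn(
                f"region {name}: no positive predictions in cohort; "
                "PPV reported as 1 by the empty-prediction convention",
                stacklevel=2,
            )
            ppv[name] = 1.0
        records = [r for c in cases for r in c.regions[name].lesions]
        curves[name] = {
            metric: running_average_by_volume(records, metric)
            for metric in ("dice", "hd95", "detected")
        }
    if not any_evaluable:
        raise DegenerateCohortError("cohort contains no evaluable lesions")
    return CohortSummary(
        detection_rate=detection, sensitivity=sensitivity, ppv=ppv, curves=curves
    )


def scores_frame(cases: list[CaseScores]) -> "pd.DataFrame":
    """Long-format per-case score table (one row per case/region/metric)."""
    import pandas as pd

    rows = []
    for c in cases:
        for name, rs in c.regions.items():
            for metric, value in (
                ("lesionwise_dice", rs.lesionwise_dice),
                ("lesionwise_hd95", rs.lesionwise_hd95),
                ("legacy_dice", rs.legacy_dice),
                ("legacy_hd95", rs.legacy_hd95),
            ):
                rows.append(
                    {
                        "case_id": c.case_id,
                        "region": name,
                        "metric": metric,
                        "value": value,
                        "TP": rs.tp,
                        "FN": rs.fn,
                        "FP": rs.fp,
                        "n_excluded": rs.n_excluded,
                    }
                )
    return pd.DataFrame(rows)


def lesions_frame(cases: list[CaseScores]) -> "pd.DataFrame":
    """Per-lesion table (case, region, unit, volume, dice, hd95, detected)."""
    import pandas as pd

    rows = [
        {
            "case_id": r.case_id,
            "region": r.region,
            "unit_id": r.unit_id,
            "volume_mm3": r.volume_mm3,
            "dice": r.dice,
            "hd95": r.hd95,
            "detected": r.detected,
        }
        for c in cases
        for rs in c.regions.values()
        for r in rs.lesions
    ]
    return pd.DataFrame(rows)


def running_average_by_volume(
    records: list[LesionRecord], metric: str = "dice"
) -> np.ndarray:
    """Running mean of a per-lesion metric over an expanding volume window.

    Lesions are sorted by ascending volume; the curve's k-th point is the
    mean of the metric over the k smallest lesions, starting from the
    smallest. Lesions tied in volume enter the window together, so the
    curve has one point per distinct volume. Returns an array of shape
    (n_points, 2) with columns (volume_threshold_mm3, running_mean);
    empty records give an empty (0, 2) array.
    """
    if metric not in ("dice", "hd95", "detected"):
        raise ValueError(f"unknown metric {metric!r}")
    if not records:
        return np.empty((0, 2))
    vols = np.array([r.volume_mm3 for r in records], float)
    vals = np.array([float(getattr(r, metric)) for r in records], float)
    order = np.argsort(vols, kind="stable")
    vols, vals = vols[order], vals[order]
    cum_mean = np.cumsum(vals) / np.arange(1, len(vals) + 1)
    # ties enter together: keep the last index of each distinct volume
    last_of_volume = np.flatnonzero(np.r_[vols[1:] != vols[:-1], True])
    return np.column_stack([vols[last_of_volume], cum_mean[last_of_volume]])
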
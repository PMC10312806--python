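"""Decomposition of ground-truth and predicted regions into lesion units.

The matcher implements the lesion-wise evaluation protocol:

1. the ground-truth (GT) region mask is dilated (1 voxel, full 3x3x3
   structuring element by default) so that small satellite lesions adjacent
   to a primary lesion merge into one evaluation unit;
2. 26-connectivity connected components of the *dilated* GT define the
   units, while each unit keeps its *undilated* GT voxels for scoring — the
   GT labels themselves are never modified;
3. every 26-connectivity component of the prediction is matched to the unit
   whose dilated support it overlaps the most (ties break toward the lower
   unit id); components overlapping no unit are false positives;
4. GT units whose undilated volume is at or below a small volumetric
   threshold (2 voxels at 1 mm isotropic) are excluded from all counts, as
   are equally small unmatched predicted components — the threshold guards
   against stray voxels from annotation error on either side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .label_io import RegionMask, RegionSpec, check_comparable

_CONN_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class EvalParams:
    """Parameters of the lesion-wise evaluation protocol.

    Attributes
    ----------
    connectivity
        Neighborhood order for connected components (6, 18 or 26).
    dilation_voxels
        Number of GT dilation iterations used to form evaluation units.
    min_lesion_voxels
        Units (and unmatched predicted components) whose volume is <= this
        many voxels are excluded from every count.
    fn_dice
        Dice contribution of a missed lesion (false negative).
    fp_fn_hd95
        Fixed HD95 penalty, in mm, charged per false negative and per false
        positive; also the supremum to which computed HD95 values are
        clipped.
    """

    connectivity: int = 26
    dilation_voxels: int = 1
    min_lesion_voxels: int = 2
    fn_dice: float = 0.0
    fp_fn_hd95: float = 374.0

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValidationError(
                f"connectivity must be 6, 18 or 26, got {self.connectivity}"
            )
        if self.dilation_voxels < 0:
            raise ValidationError("dilation_voxels must be >= 0")
        if self.min_lesion_voxels < 0:
            raise ValidationError("min_lesion_voxels must be >= 0")
        if self.fp_fn_hd95 <= 0:
            raise ValidationError("fp_fn_hd95 must be > 0")


@dataclass
class ComponentLabeling:
    """Connected components of a binary mask.

    ``component_ids`` holds 0 for background and 1..n for foreground, with
    ids assigned by first-voxel order in a lexicographic (C-order) scan so
    the labeling is deterministic.
    """

    component_ids: np.ndarray
    n_components: int
    volumes_mm3: np.ndarray


@dataclass
class GtUnit:
    """One ground-truth evaluation unit (possibly several merged lesions)."""

    unit_id: int
    gt_voxels: np.ndarray  # boolean mask of the UNDILATED GT voxels
    dilated_voxels: np.ndarray  # boolean mask of the unit's dilated support
    volume_mm3: float
    matched_pred_voxels: np.ndarray | None = None  # union of matched components
    status: str = "FN"  # one of TP / FN / excluded


@dataclass
class LesionMatchResult:
    """Outcome of matching one predicted region against one GT region."""

    region: RegionSpec
    gt_units: list[GtUnit]
    fp_components: list[np.ndarray]  # boolean masks of FP predicted components
    tp: int
    fn: int
    fp: int
    n_excluded: int
    params: EvalParams
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)


def connected_components(
    mask: RegionMask | np.ndarray, connectivity: int = 26
) -> ComponentLabeling:
    """Label connected components with deterministic scan-order ids.

    Two foreground voxels belong to the same component iff they are linked
    by a chain of neighbors under the requested connectivity (26 = faces,
    edges and corners).
    """
    if connectivity not in _CONN_STRUCTS:
        raise ValidationError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    voxels = mask.voxels if isinstance(mask, RegionMask) else np.asarray(mask, bool)
    spacing = mask.spacing if isinstance(mask, RegionMask) else (1.0, 1.0, 1.0)
    labels, n = ndimage.label(voxels, structure=_CONN_STRUCTS[connectivity])
    if n > 0:
        # relabel so ids follow the first occurrence in C-order scan
        flat = labels.ravel()
        first_idx = np.full(n + 1, flat.size, dtype=np.int64)
        nz = np.flatnonzero(flat)
        # reversed so the smallest index wins
        first_idx[flat[nz[::-1]]] = nz[::-1]
        order = np.argsort(first_idx[1:], kind="stable")
        remap = np.zeros(n + 1, dtype=labels.dtype)
        remap[order + 1] = np.arange(1, n + 1)
        labels = remap[labels]
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    voxel_vol = float(np.prod(spacing))
    return ComponentLabeling(
        component_ids=labels,
        n_components=int(n),
        volumes_mm3=counts.astype(float) * voxel_vol,
    )


def dilate(mask: RegionMask | np.ndarray, iterations: int = 1) -> np.ndarray:
    """Binary dilation with the full 3x3x3 (26-neighbor) structuring element.

    ``iterations=0`` is the identity. The input mask is always a subset of
    the result.
    """
    if iterations < 0:
        raise ValidationError("dilation iterations must be >= 0")
    voxels = mask.voxels if isinstance(mask, RegionMask) else np.asarray(mask, bool)
    if iterations == 0:
        return voxels.copy()
    return ndimage.binary_dilation(
        voxels, structure=_CONN_STRUCTS[26], iterations=iterations
    )


def match_lesions(
    gt: RegionMask, pred: RegionMask, params: EvalParams | None = None
) -> LesionMatchResult:
    """Decompose a GT/prediction region pair into matched lesion units.

    Returns the per-unit TP/FN/excluded status, the false-positive
    predicted components, and the TP/FN/FP counts that feed the lesion-wise
    score denominators.
    """
    params = params or EvalParams()
    check_comparable(gt, pred)
    voxel_vol = gt.voxel_volume_mm3

    dilated_gt = dilate(gt, params.dilation_voxels)
    unit_cc = connected_components(
        RegionMask(dilated_gt, gt.region, gt.spacing), params.connectivity
    )
    pred_cc = connected_components(pred, params.connectivity)

    units: list[GtUnit] = []
    for uid in range(1, unit_cc.n_components + 1):
        support = unit_cc.component_ids == uid
        gt_vox = support & gt.voxels
        n_gt = int(gt_vox.sum())
        unit = GtUnit(
            unit_id=uid,
            gt_voxels=gt_vox,
            dilated_voxels=support,
            volume_mm3=n_gt * voxel_vol,
        )
        if n_gt <= params.min_lesion_voxels:
            unit.status = "excluded"
        units.append(unit)

    # assign each predicted component to the unit with maximal overlap
    fp_components: list[np.ndarray] = []
    unit_ids_img = unit_cc.component_ids
    for cid in range(1, pred_cc.n_components + 1):
        comp = pred_cc.component_ids == cid
        overlapped = unit_ids_img[comp]
        overlapped = overlapped[overlapped > 0]
        if overlapped.size == 0:
            if int(comp.sum()) > params.min_lesion_voxels:
                fp_components.append(comp)
            continue
        counts = np.bincount(overlapped)
        best_uid = int(np.argmax(counts))  # argmax takes the lowest id on ties
        unit = units[best_uid - 1]
        if unit.matched_pred_voxels is None:
            unit.matched_pred_voxels = comp.copy()
        else:
            unit.matched_pred_voxels |= comp
        if unit.status != "excluded":
            unit.status = "TP"

    tp = sum(1 for u in units if u.status == "TP")
    fn = sum(1 for u in units if u.status == "FN")
    n_excluded = sum(1 for u in units if u.status == "excluded")
    return LesionMatchResult(
        region=gt.region,
        gt_units=units,
        fp_components=fp_components,
        tp=tp,
        fn=fn,
        fp=len(fp_components),
        n_excluded=n_excluded,
        params=params,
        spacing=gt.spacing,
    )
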
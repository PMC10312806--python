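"""NIfTI label-map I/O, label-convention validation, and region extraction.

Label maps follow the current multi-class brain tumor convention:

* 0 — background
* 1 — non-enhancing tumor core (NETC)
* 2 — surrounding non-enhancing FLAIR hyperintensity (SNFH)
* 3 — enhancing tumor (ET)

The three evaluation regions are composites of these labels:
ET = {3}, TC (tumor core) = {1, 3}, WT (whole tumor) = {1, 2, 3}.
Legacy datasets that encoded enhancing tumor as label 4 are accepted only
behind an explicit remap flag; anything else outside {0, 1, 2, 3} is a hard
validation error rather than being silently remapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ComparisonError, FormatError, ValidationError

logger = logging.getLogger(__name__)

ALLOWED_LABELS = frozenset({0, 1, 2, 3})

LABEL_NETC = 1
LABEL_SNFH = 2
LABEL_ET = 3


@dataclass(frozen=True)
class RegionSpec:
    """A named evaluation region defined as a subset of tissue labels."""

    name: str
    member_labels: frozenset[int]


#: The three evaluation regions, in canonical reporting order.
REGIONS: dict[str, RegionSpec] = {
    "ET": RegionSpec("ET", frozenset({3})),
    "TC": RegionSpec("TC", frozenset({1, 3})),
    "WT": RegionSpec("WT", frozenset({1, 2, 3})),
}


@dataclass
class LabelMap:
    """A 3D integer label volume with voxel spacing and affine.

    Parameters
    ----------
    voxels
        3D array of non-negative integer labels.
    spacing
        Per-axis voxel size in mm. Defaults to 1 mm isotropic.
    affine
        Voxel-to-world mapping; defaults to a diagonal affine built from
        ``spacing``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"label volume must be 3D, got {self.voxels.ndim}D"
            )
        if not np.issubdtype(self.voxels.dtype, np.integer):
            if np.issubdtype(self.voxels.dtype, np.floating) and np.all(
                self.voxels == np.round(self.voxels)
            ):
                self.voxels = self.voxels.astype(np.int16)
            else:
                raise FormatError(
                    f"label volume must be integer-valued, got dtype {self.voxels.dtype}"
                )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(
                f"spacing must be three strictly positive values, got {self.spacing}"
            )
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self._validate_labels()

    def _validate_labels(self) -> None:
        present = np.unique(self.voxels)
        bad = sorted(int(v) for v in present if int(v) not in ALLOWED_LABELS)
        if bad:
            raise ValidationError(
                f"labels outside the allowed set {sorted(ALLOWED_LABELS)}: {bad}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class RegionMask:
    """A binary mask for one evaluation region of a :class:`LabelMap`."""

    voxels: np.ndarray
    region: RegionSpec
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def read_label_map(path: str | Path, remap_legacy_et: bool = False) -> LabelMap:
    """Read a NIfTI label volume and validate the label convention.

    Parameters
    ----------
    path
        Path to a ``.nii`` or ``.nii.gz`` file holding a 3D integer volume.
    remap_legacy_et
        If true, legacy enhancing-tumor voxels encoded as label 4 are
        remapped to label 3 (logged); otherwise label 4 is a validation
        error like any other out-of-convention value.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        if np.all(data == np.round(data)):
            data = data.astype(np.int16)
        else:
            raise FormatError(f"{path}: non-integer voxel values")
    data = data.astype(np.int16, copy=False)
    if remap_legacy_et and np.any(data == 4):
        n = int(np.sum(data == 4))
        logger.info("%s: remapping %d legacy label-4 voxels to label 3", path, n)
        data = np.where(data == 4, np.int16(3), data)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    try:
        return LabelMap(voxels=data, spacing=spacing, affine=np.asarray(img.affine))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_label_map(lm: LabelMap, path: str | Path) -> None:
    """Write a :class:`LabelMap` as NIfTI (dtype uint8)."""
    img = nib.Nifti1Image(lm.voxels.astype(np.uint8), lm.affine)
    img.header.set_zooms(lm.spacing)
    nib.save(img, str(path))


def extract_region(lm: LabelMap, region: RegionSpec | str) -> RegionMask:
    """Binary mask of the voxels whose label belongs to the region.

    The result depends only on the voxel labels, never on the affine.
    """
    if isinstance(region, str):
        try:
            region = REGIONS[region]
        except KeyError:
            raise ValidationError(
                f"unknown region {region!r}; expected one of {sorted(REGIONS)}"
            ) from None
    mask = np.isin(lm.voxels, list(region.member_labels))
    return RegionMask(voxels=mask, region=region, spacing=lm.spacing)


def check_comparable(gt: LabelMap | RegionMask, pred: LabelMap | RegionMask) -> None:
    """Raise unless the two volumes share shape and spacing."""
    if gt.shape != pred.shape:
        raise ComparisonError(
            f"shape mismatch: ground truth {gt.shape} vs prediction {pred.shape}"
        )
    if not np.allclose(gt.spacing, pred.spacing):
        raise ComparisonError(
            f"spacing mismatch: ground truth {gt.spacing} vs prediction {pred.spacing}"
        )
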
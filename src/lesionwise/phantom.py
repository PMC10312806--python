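"""Synthetic multi-lesion metastasis phantoms with known ground truth.

The generator places non-overlapping spherical lesions on an isotropic
grid. Each lesion is an enhancing-tumor ball (label 3), optionally with a
necrotic core (label 1) and always surrounded by an edema halo (label 2)
of configurable thickness. Defaults emulate the lesion statistics of
multi-institutional metastasis cohorts: a per-case lesion count of
1 + Poisson(1.5) (median 2), and a lognormal enhancing-tumor radius with
median 2.8 mm (median discrete ET volume on the order of 100 mm^3,
spanning sub-5 mm detections to centimeter-scale lesions).

``perturb_prediction`` degrades a phantom into a synthetic "model output"
with the canonical failure modes of automated metastasis segmentation:
whole-lesion misses whose probability grows as lesion volume shrinks,
spurious stand-alone blobs, and boundary jitter. It returns a manifest of
the planned true-positive/false-negative/false-positive counts per region
so the evaluation pipeline can be checked end to end against known truth.

Lesions are geometric solids, not textured images: the evaluation consumes
label maps only, so no intensity simulation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import PackingError, ValidationError
from .label_io import LabelMap

REGION_NAMES = ("ET", "TC", "WT")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and sampling distributions for ground-truth phantoms.

    All length units are mm (equal to voxels at the default 1 mm grid).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: lesion count is 1 + Poisson(lesion_count_lambda)
    lesion_count_lambda: float = 1.5
    #: lognormal ET radius: exp(N(log(radius_median), radius_sigma))
    radius_median: float = 2.8
    radius_sigma: float = 0.55
    radius_min: float = 1.5
    radius_max: float = 12.0
    #: probability that a lesion (of sufficient radius) has a necrotic core
    netc_prob: float = 0.3
    netc_core_fraction: float = 0.4
    #: edema halo thickness beyond the ET ball
    halo_mm: float = 2.0
    #: minimum surface-to-surface separation between lesions (incl. halos);
    #: must exceed 3*sqrt(3) mm so 1-voxel dilation can never merge two
    #: lesions (26-neighborhood reach is Chebyshev, worst case diagonal)
    min_separation: float = 6.0
    border_margin: float = 2.0
    max_place_attempts: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_min <= 0 or self.radius_max < self.radius_min:
            raise ValidationError("need 0 < radius_min <= radius_max")
        if self.lesion_count_lambda < 0:
            raise ValidationError("lesion_count_lambda must be >= 0")
        if self.halo_mm < 0 or self.min_separation < 0:
            raise ValidationError("halo_mm and min_separation must be >= 0")


@dataclass(frozen=True)
class PerturbationConfig:
    """Controlled degradation of a phantom into a synthetic prediction."""

    #: whole-lesion miss probability: dropout_max * 2**(-volume / halflife)
    dropout_max: float = 0.8
    dropout_volume_halflife: float = 100.0
    #: number of spurious blobs is Poisson(fp_count_lambda)
    fp_count_lambda: float = 1.0
    fp_radius_min: float = 1.5
    fp_radius_max: float = 4.0
    #: ET radius jitter amplitude in voxels (0 disables boundary jitter)
    jitter_amplitude: int = 0
    #: clearance between a spurious blob and any GT lesion, beyond the
    #: reach of GT dilation during matching
    fp_clearance: float = 6.0
    max_place_attempts: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_max <= 1):
            raise ValidationError("dropout_max must be in [0, 1]")
        if self.jitter_amplitude < 0:
            raise ValidationError("jitter_amplitude must be >= 0")


def _ball_mask(shape: tuple[int, ...], center: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask of voxels whose center lies within ``radius`` of ``center``."""
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, shape)
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    out = np.zeros(shape, bool)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = d2 <= radius**2
    return out


def _paint_lesion(
    vol: np.ndarray,
    center: np.ndarray,
    et_radius: float,
    core_radius: float,
    halo_mm: float,
) -> dict[str, int]:
    """Paint halo(2) / ET(3) / core(1) onto ``vol``; return label voxel counts."""
    shape = vol.shape
    if halo_mm > 0:
        halo = _ball_mask(shape, center, et_radius + halo_mm)
        vol[halo & (vol == 0)] = 2
    et = _ball_mask(shape, center, et_radius)
    vol[et] = 3
    n_core = 0
    if core_radius > 0:
        core = _ball_mask(shape, center, core_radius)
        vol[core] = 1
        n_core = int(core.sum())
    n_et = int(et.sum()) - n_core
    n_halo = 0
    if halo_mm > 0:
        n_halo = int((halo & ~et).sum())
    return {"NETC": n_core, "ET": n_et, "SNFH": n_halo}


def _sample_lesions(config: PhantomConfig, rng: np.random.Generator) -> list[dict]:
    """Sample non-overlapping lesion geometries by rejection."""
    n_lesions = 1 + int(rng.poisson(config.lesion_count_lambda))
    shape = np.asarray(config.shape, float)
    lesions: list[dict] = []
    for lid in range(1, n_lesions + 1):
        radius = float(
            np.clip(
                np.exp(rng.normal(np.log(config.radius_median), config.radius_sigma)),
                config.radius_min,
                config.radius_max,
            )
        )
        outer = radius + config.halo_mm
        placed = False
        for _ in range(config.max_place_attempts):
            lo = outer + config.border_margin
            hi = shape - 1 - outer - config.border_margin
            if np.any(hi < lo):
                break  # lesion cannot fit this grid at all
            center = rng.uniform(lo, hi)
            ok = all(
                np.linalg.norm(center - l["center"])
                >= outer + l["radius"] + config.halo_mm + config.min_separation
                for l in lesions
            )
            if ok:
                has_core = (
                    radius >= 2.5
                    and config.netc_prob > 0
                    and rng.random() < config.netc_prob
                )
                core_radius = config.netc_core_fraction * radius if has_core else 0.0
                lesions.append(
                    {"id": lid, "center": center, "radius": radius,
                     "core_radius": core_radius}
                )
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could not place lesion {lid} (radius {radius:.1f} mm) after "
                f"{config.max_place_attempts} attempts on grid {config.shape}"
            )
    return lesions


def _render(
    lesions: list[dict], shape: tuple[int, int, int], halo_mm: float
) -> tuple[np.ndarray, list[dict[str, int]]]:
    vol = np.zeros(shape, dtype=np.int16)
    counts = [
        _paint_lesion(vol, l["center"], l["radius"], l["core_radius"], halo_mm)
        for l in lesions
    ]
    return vol, counts


def generate_phantom(config: PhantomConfig | None = None) -> tuple[LabelMap, dict]:
    """Generate one ground-truth phantom and its truth manifest.

    Returns the label map plus a JSON-serializable manifest listing each
    lesion's center, radii, and per-label / per-region voxel volumes.
    Deterministic under ``config.seed``.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(config.seed)
    lesions = _sample_lesions(config, rng)
    vol, counts = _render(lesions, config.shape, config.halo_mm)
    voxel_vol = float(np.prod(config.spacing))
    manifest = {
        "shape": list(config.shape),
        "spacing": list(config.spacing),
        "seed": config.seed,
        "lesions": [
            {
                "id": l["id"],
                "center": [float(c) for c in l["center"]],
                "et_radius_mm": l["radius"],
                "core_radius_mm": l["core_radius"],
                "halo_mm": config.halo_mm,
                "label_volumes_mm3": {k: v * voxel_vol for k, v in c.items()},
                "region_volumes_mm3": {
                    "ET": c["ET"] * voxel_vol,
                    "TC": (c["ET"] + c["NETC"]) * voxel_vol,
                    "WT": (c["ET"] + c["NETC"] + c["SNFH"]) * voxel_vol,
                },
            }
            for l, c in zip(lesions, counts)
        ],
    }
    return LabelMap(voxels=vol, spacing=config.spacing), manifest


def perturb_prediction(
    gt: LabelMap, manifest: dict, config: PerturbationConfig | None = None
) -> tuple[LabelMap, dict]:
    """Degrade a phantom into a synthetic prediction with planned errors.

    Whole lesions are dropped with a probability that decays with lesion
    volume (halving every ``dropout_volume_halflife`` mm^3), spurious
    enhancing blobs are inserted well clear of every GT lesion, and
    surviving lesion boundaries are jittered by re-rendering with a
    perturbed ET radius. The returned expected-outcome manifest records
    the planned per-region TP/FN/FP counts, which the evaluation must
    reproduce exactly whenever ``jitter_amplitude`` is 0.
    """
    config = config or PerturbationConfig()
    rng = np.random.default_rng(config.seed)
    shape = tuple(manifest["shape"])
    halo_mm = manifest["lesions"][0]["halo_mm"] if manifest["lesions"] else 0.0

    surviving: list[dict] = []
    dropped_ids: list[int] = []
    for entry in manifest["lesions"]:
        vol_et = entry["region_volumes_mm3"]["ET"]
        p_drop = config.dropout_max * 2.0 ** (-vol_et / config.dropout_volume_halflife)
        if rng.random() < p_drop:
            dropped_ids.append(entry["id"])
            continue
        radius = entry["et_radius_mm"]
        if config.jitter_amplitude > 0:
            radius = max(
                1.0,
                radius + float(rng.integers(-config.jitter_amplitude,
                                            config.jitter_amplitude + 1)),
            )
        surviving.append(
            {
                "id": entry["id"],
                "center": np.asarray(entry["center"]),
                "radius": radius,
                "core_radius": entry["core_radius_mm"],
            }
        )

    pred, _ = _render(surviving, shape, halo_mm)

    # spurious stand-alone enhancing blobs, clear of all GT lesions
    n_fp = int(rng.poisson(config.fp_count_lambda))
    fp_blobs: list[dict] = []
    shape_f = np.asarray(shape, float)
    for _ in range(n_fp):
        radius = float(rng.uniform(config.fp_radius_min, config.fp_radius_max))
        placed = False
        for _ in range(config.max_place_attempts):
            lo = radius + 1.0
            hi = shape_f - 1 - radius - 1.0
            if np.any(hi < lo):
                break
            center = rng.uniform(lo, hi)
            clear_gt = all(
                np.linalg.norm(center - np.asarray(e["center"]))
                >= radius + e["et_radius_mm"] + e["halo_mm"] + config.fp_clearance
                for e in manifest["lesions"]
            )
            clear_fp = all(
                np.linalg.norm(center - np.asarray(b["center"]))
                >= radius + b["radius_mm"] + config.fp_clearance
                for b in fp_blobs
            )
            if clear_gt and clear_fp:
                blob = _ball_mask(shape, center, radius)
                pred[blob] = 3
                fp_blobs.append(
                    {"center": [float(c) for c in center], "radius_mm": radius}
                )
                placed = True
                break
        if not placed:
            raise PackingError(
                "could not place a spurious blob with the required clearance"
            )

    n_tp = len(surviving)
    expected = {
        "dropped_lesion_ids": dropped_ids,
        "fp_blobs": fp_blobs,
        "expected_counts": {
            region: {"TP": n_tp, "FN": len(dropped_ids), "FP": len(fp_blobs)}
            for region in REGION_NAMES
        },
        "jitter_amplitude": config.jitter_amplitude,
        "seed": config.seed,
    }
    return LabelMap(voxels=pred, spacing=tuple(manifest["spacing"])), expected
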
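"""Multi-rater binary mask fusion for the pre-segmentation stage.

Three fusion rules are used when combining candidate segmentations from
multiple automated raters into a single label map:

* **STAPLE** (simultaneous truth and performance level estimation) for the
  edema/FLAIR-hyperintensity compartment: an EM algorithm that alternates
  between estimating the voxel-wise posterior probability of the hidden
  true mask and re-estimating each rater's sensitivity ``p_j`` and
  specificity ``q_j``, so systematically over- or under-segmenting raters
  are down-weighted.
* **Minority-vote union** for enhancing tumor: a voxel is foreground if
  *any* rater marks it — small metastases are easy to miss, so a single
  detection is kept.
* **Precedence composition**: the non-enhancing core (label 1) overlays
  enhancing tumor (label 3), which overlays edema (label 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .label_io import LabelMap

_EPS = 1e-7


@dataclass
class RaterStack:
    """Aligned binary masks from multiple automated raters."""

    masks: list[np.ndarray]
    rater_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.masks = [np.asarray(m, bool) for m in self.masks]
        if not self.masks:
            raise ValidationError("rater stack is empty")
        shape = self.masks[0].shape
        if any(m.shape != shape for m in self.masks):
            raise ValidationError("all rater masks must share one shape")
        if self.rater_ids is None:
            self.rater_ids = [f"rater{i}" for i in range(len(self.masks))]
        if len(self.rater_ids) != len(self.masks):
            raise ValidationError("rater_ids length must match masks")

    @property
    def n_raters(self) -> int:
        return len(self.masks)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.masks[0].shape


@dataclass
class StapleResult:
    """Consensus estimate and per-rater performance parameters."""

    consensus_probability: np.ndarray
    consensus_mask: np.ndarray
    sensitivity: np.ndarray  # p_j, per rater
    specificity: np.ndarray  # q_j, per rater
    n_iterations: int
    converged: bool
    log_likelihood: list[float]  # one entry per EM iteration, non-decreasing


def staple(
    stack: RaterStack,
    prior: float | np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    threshold: float = 0.5,
    per_component: bool = False,
) -> StapleResult:
    """Binary STAPLE fusion via expectation-maximization.

    Parameters
    ----------
    stack
        At least two aligned binary rater masks.
    prior
        Scalar (or voxel-wise) prior probability of foreground. Defaults
        to the mean foreground fraction across raters.
    tol
        Convergence threshold on the maximum change of any sensitivity or
        specificity between iterations.
    max_iter
        EM iteration cap.
    threshold
        Posterior cut for the returned ``consensus_mask``.
    per_component
        If true, run STAPLE independently on each connected component of
        the union support (plus nothing outside it), limiting the
        background-dominance bias of a global run. Default off: the global
        run over the full volume.
    """
    if stack.n_raters < 2:
        raise ValidationError("STAPLE requires at least 2 raters")
    if not (0 < threshold < 1):
        raise ValidationError("threshold must be in (0, 1)")

    if per_component:
        return _staple_per_component(stack, prior, tol, max_iter, threshold)

    d = np.stack([m.ravel() for m in stack.masks]).astype(np.float64)  # J x N
    n_raters, n_vox = d.shape

    for j, m in enumerate(stack.masks):
        frac = float(d[j].mean())
        if frac in (0.0, 1.0):
            warnings.warn(
                f"rater {stack.rater_ids[j]} has an "
                f"{'empty' if frac == 0.0 else 'full'} mask; performance "
                "parameters will be clamped",
                stacklevel=2,
            )

    if prior is None:
        prior_arr = np.full(n_vox, float(d.mean()))
    elif np.isscalar(prior):
        if not (0 < prior < 1):
            raise ValidationError("scalar prior must be in (0, 1)")
        prior_arr = np.full(n_vox, float(prior))
    else:
        prior_arr = np.asarray(prior, float).ravel()
        if prior_arr.size != n_vox:
            raise ValidationError("voxel-wise prior shape must match the masks")
    prior_arr = np.clip(prior_arr, _EPS, 1 - _EPS)

    p = np.full(n_raters, 0.99999)  # sensitivity
    q = np.full(n_raters, 0.99999)  # specificity
    log_likelihood: list[float] = []
    converged = False
    w = prior_arr.copy()
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: posterior of foreground given votes and current (p, q)
        log_a = np.log(prior_arr) + d.T @ np.log(p) + (1 - d).T @ np.log1p(-p)
        log_b = np.log1p(-prior_arr) + d.T @ np.log1p(-q) + (1 - d).T @ np.log(q)
        m = np.maximum(log_a, log_b)
        denom = np.exp(log_a - m) + np.exp(log_b - m)
        w = np.exp(log_a - m) / denom
        log_likelihood.append(float(np.sum(m + np.log(denom))))
        # M-step: re-estimate sensitivity/specificity from posteriors
        sw = w.sum()
        snw = n_vox - sw
        p_new = np.clip((d @ w) / max(sw, _EPS), _EPS, 1 - _EPS)
        q_new = np.clip(((1 - d) @ (1 - w)) / max(snw, _EPS), _EPS, 1 - _EPS)
        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break

    prob = w.reshape(stack.shape)
    return StapleResult(
        consensus_probability=prob,
        consensus_mask=prob >= threshold,
        sensitivity=p,
        specificity=q,
        n_iterations=it,
        converged=converged,
        log_likelihood=log_likelihood,
    )


def _staple_per_component(stack, prior, tol, max_iter, threshold):
    union = np.zeros(stack.shape, bool)
    for m in stack.masks:
        union |= m
    labels, n = ndimage.label(union, structure=np.ones((3, 3, 3), bool))
    prob = np.zeros(stack.shape)
    p_acc = np.zeros(stack.n_raters)
    q_acc = np.zeros(stack.n_raters)
    ll: list[float] = []
    iters = 0
    converged = True
    for cid in range(1, n + 1):
        comp = labels == cid
        sub = RaterStack(
            [m[comp] .reshape(-1, 1, 1) for m in stack.masks], stack.rater_ids
        )
        res = staple(sub, prior=prior, tol=tol, max_iter=max_iter, threshold=threshold)
        prob[comp] = res.consensus_probability.ravel()
        p_acc += res.sensitivity
        q_acc += res.specificity
        iters = max(iters, res.n_iterations)
        converged &= res.converged
        ll = res.log_likelihood  # last component's trace, per-region runs are independent
    k = max(n, 1)
    return StapleResult(
        consensus_probability=prob,
        consensus_mask=prob >= threshold,
        sensitivity=p_acc / k if n else np.full(stack.n_raters, np.nan),
        specificity=q_acc / k if n else np.full(stack.n_raters, np.nan),
        n_iterations=iters,
        converged=converged,
        log_likelihood=ll,
    )


def minority_vote_union(stack: RaterStack, min_votes: int = 1) -> np.ndarray:
    """Voxels marked foreground by at least ``min_votes`` raters.

    The default threshold of one vote makes this the plain union: any
    voxel any rater identifies is kept, which favors sensitivity to small
    lesions over specificity.
    """
    if min_votes < 1:
        raise ValidationError("min_votes must be >= 1")
    votes = np.zeros(stack.shape, dtype=np.int32)
    for m in stack.masks:
        votes += m
    return votes >= min_votes


def compose_labels(
    snfh_mask: np.ndarray,
    et_mask: np.ndarray,
    netc_mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LabelMap:
    """Compose fused tissue masks into one label map.

    Precedence is NETC (1) over ET (3) over SNFH (2) over background: the
    non-enhancing core overlays both other labels wherever masks overlap.
    """
    snfh = np.asarray(snfh_mask, bool)
    et = np.asarray(et_mask, bool)
    netc = np.asarray(netc_mask, bool)
    if not (snfh.shape == et.shape == netc.shape):
        raise ValidationError("tissue masks must share one shape")
    out = np.zeros(snfh.shape, dtype=np.int16)
    out[snfh] = 2
    out[et] = 3
    out[netc] = 1
    return LabelMap(voxels=out, spacing=spacing)
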
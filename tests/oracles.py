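"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid scipy.ndimage / cKDTree code paths: connected
components via breadth-first flood fill, dilation via an explicit
neighborhood max, HD95 via all-pairs boundary distances, and the
permutation test via exhaustive sign-flip enumeration.
"""

from collections import deque
from itertools import product

import numpy as np

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx, dy, dz in product((-1, 0, 1), repeat=3)
    if (dx, dy, dz) != (0, 0, 0)
]


def flood_fill_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """BFS connected components over the 26-neighborhood, scan-order ids."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, dtype=int)
    next_id = 0
    for idx in np.ndindex(mask.shape):
        if mask[idx] and labels[idx] == 0:
            next_id += 1
            queue = deque([idx])
            labels[idx] = next_id
            while queue:
                x, y, z = queue.popleft()
                for dx, dy, dz in NEIGHBORS_26:
                    n = (x + dx, y + dy, z + dz)
                    if (
                        all(0 <= c < s for c, s in zip(n, mask.shape))
                        and mask[n]
                        and labels[n] == 0
                    ):
                        labels[n] = next_id
                        queue.append(n)
    return labels, next_id


def brute_dilate(mask: np.ndarray, iterations: int) -> np.ndarray:
    """Voxel-wise max over the 3x3x3 neighborhood, repeated."""
    out = np.asarray(mask, bool).copy()
    for _ in range(iterations):
        new = out.copy()
        for idx in np.ndindex(out.shape):
            if out[idx]:
                continue
            x, y, z = idx
            for dx, dy, dz in NEIGHBORS_26:
                n = (x + dx, y + dy, z + dz)
                if all(0 <= c < s for c, s in zip(n, out.shape)) and out[n]:
                    new[idx] = True
                    break
        out = new
    return out


def brute_boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with a background 6-neighbor (border = background)."""
    mask = np.asarray(mask, bool)
    coords = []
    for idx in np.argwhere(mask):
        x, y, z = idx
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            n = (x + d[0], y + d[1], z + d[2])
            if not all(0 <= c < s for c, s in zip(n, mask.shape)) or not mask[n]:
                coords.append(idx)
                break
    return np.array(coords).reshape(-1, 3)


def brute_hd95(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th percentile of pooled all-pairs nearest surface distances."""
    sp = np.asarray(spacing, float)
    pa = brute_boundary(a) * sp
    pb = brute_boundary(b) * sp
    dmat = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    pooled = np.concatenate([dmat.min(axis=1), dmat.min(axis=0)])
    return float(np.percentile(pooled, 95))


def exhaustive_signflip_p(a, b, two_sided=True) -> float:
    """Exact sign-flip p-value over all 2^n within-subject swaps."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    obs = d.mean()
    count = 0
    for signs in product((1.0, -1.0), repeat=n):
        stat = float(np.dot(signs, d)) / n
        hit = abs(stat) >= abs(obs) - 1e-12 if two_sided else stat >= obs - 1e-12
        count += hit
    return count / 2**n
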
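"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths of the package: exhaustive
enumeration for the graph-cut energy, voxel counting for overlap and
volume metrics, all-pairs distance scans for distance fields and
surface metrics.
"""

import itertools

import numpy as np
from scipy.spatial.distance import cdist


def brute_force_min_energy(unary, pairs, weights, lam):
    """Exhaustive minimum of the two-label energy over all labellings."""
    n = unary.shape[0]
    labelings = np.array(list(itertools.product([0, 1], repeat=n)),
                         dtype=np.int64)
    energies = lam * np.where(labelings == 1, unary[:, 1], unary[:, 0]).sum(axis=1)
    for (a, b), w in zip(np.asarray(pairs).reshape(-1, 2), weights):
        energies = energies + (1.0 - lam) * w * (labelings[:, a] != labelings[:, b])
    best = int(np.argmin(energies))
    return float(energies[best]), labelings[best]


def brute_force_distance(mask_data, spacing):
    """Signed distance of every voxel to the nearest boundary voxel.

    The boundary set is found by an explicit neighbour scan: mask voxels
    with at least one 6-neighbour outside the mask (grid-border mask
    voxels do not count).  Distance is an all-pairs minimum; the sign is
    negative inside the mask.
    """
    spacing = np.asarray(spacing, dtype=float)
    boundary = np.zeros_like(mask_data)
    idx = np.argwhere(mask_data)
    shape = mask_data.shape
    for i, j, k in idx:
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2] \
                    and not mask_data[ni, nj, nk]:
                boundary[i, j, k] = True
                break
    bpts = np.argwhere(boundary) * spacing
    every = np.argwhere(np.ones_like(mask_data)) * spacing
    d = cdist(every, bpts).min(axis=1)
    out = np.where(mask_data.ravel(), -d, d)
    return out.reshape(mask_data.shape)


def counting_dice(a, b):
    inter = np.logical_and(a, b).sum()
    total = a.sum() + b.sum()
    return 100.0 if total == 0 else 100.0 * 2.0 * inter / total


def counting_volume_diff_ml(a, b, spacing):
    vox = float(np.prod(spacing))
    return abs(int(a.sum()) - int(b.sum())) * vox / 1000.0


def counting_artefact_pct(seg, artefact):
    return 100.0 * np.logical_and(seg, artefact).sum() / artefact.sum()


def double_loop_rmse(gt_points, test_points):
    """RMS of per-gt-point minimum distances, via an explicit all-pairs scan."""
    d = cdist(np.asarray(gt_points), np.asarray(test_points))
    return float(np.sqrt(np.mean(d.min(axis=1) ** 2)))
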
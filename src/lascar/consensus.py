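"""STAPLE consensus: a probabilistic reference standard from several raters.

STAPLE (Simultaneous Truth And Performance Level Estimation) treats the
unknown true segmentation as a hidden binary field and each rater j as a
Bernoulli channel with sensitivity p_j and specificity q_j.  EM
alternates a voxelwise posterior W of the true label (E-step) with
closed-form updates of (p_j, q_j) (M-step); the complete-data
log-likelihood is non-decreasing.  The consensus mask thresholds W,
conventionally at 0.7.

Computation is restricted to a bounding region (the union of the rater
masks dilated 10 mm by default) so the background class stays
informative on large, mostly-empty grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import BinaryMask
from .wall_model import dilate_mm


@dataclass(frozen=True)
class StapleResult:
    """Posterior scar probability map and per-rater performance parameters."""

    probability: np.ndarray                  # full-grid W in [0, 1]
    sensitivities: np.ndarray                # p_j
    specificities: np.ndarray                # q_j
    iterations: int
    prior: float
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]


def staple_posterior(votes: np.ndarray, p: np.ndarray, q: np.ndarray,
                     prior) -> np.ndarray:
    """E-step: posterior of true foreground given rater votes.

    ``votes`` is (R, V) binary; ``prior`` is a scalar or length-V array.
    """
    d = votes.astype(float)
    log_a = (d * np.log(p)[:, None] + (1 - d) * np.log(1 - p)[:, None]).sum(axis=0)
    log_b = ((1 - d) * np.log(q)[:, None] + d * np.log(1 - q)[:, None]).sum(axis=0)
    pr = np.clip(np.asarray(prior, dtype=float), 1e-12, 1 - 1e-12)
    logit = np.log(pr) - np.log1p(-pr) + log_a - log_b
    return 1.0 / (1.0 + np.exp(-logit))


def staple_fit(raters, prior=None, tol: float = 1e-6, max_iter: int = 200,
               bounding_mm: float = 10.0) -> StapleResult:
    """Fit the STAPLE model to >= 2 rater masks on a common grid."""
    raters = list(raters)
    if len(raters) < 2:
        raise ValueError("need at least 2 raters")
    ref = raters[0]
    for r in raters[1:]:
        ref.check_same_grid(r)
    stack = np.stack([r.data for r in raters])
    if not stack.any():
        raise ValueError("degenerate input: all raters empty")
    if stack.all():
        raise ValueError("degenerate input: all raters full")

    union = ref.with_data(stack.any(axis=0))
    region = dilate_mm(union, bounding_mm).data
    votes = stack[:, region]  # (R, V)
    n_raters, n_vox = votes.shape

    if prior is None:
        pi = float(votes.mean())
    else:
        pi = float(prior)
    pi = min(max(pi, 1e-6), 1 - 1e-6)

    p = np.full(n_raters, 0.9)
    q = np.full(n_raters, 0.9)
    w = None
    iterations = 0
    for iterations in range(1, max_iter + 1):
        w = staple_posterior(votes, p, q, pi)
        sw, swc = w.sum(), n_vox - w.sum()
        p_new = np.clip((votes * w).sum(axis=1) / max(sw, 1e-300),
                        1e-6, 1 - 1e-6)
        q_new = np.clip(((1 - votes) * (1 - w)).sum(axis=1) / max(swc, 1e-300),
                        1e-6, 1 - 1e-6)
        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if delta < tol:
            break
    w = staple_posterior(votes, p, q, pi)

    prob = np.zeros(ref.shape, dtype=float)
    prob[region] = w
    return StapleResult(prob, p, q, iterations, pi, ref.spacing, ref.origin)


def consensus_mask(result: StapleResult, threshold: float = 0.7) -> BinaryMask:
    """Voxels whose posterior probability exceeds the threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return BinaryMask(result.probability > threshold, result.spacing,
                      result.origin, role="scar")
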
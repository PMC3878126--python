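"""The challenge segmentation algorithms and the fixed reference models.

All methods share one contract: ``segment_*(vol, endo-or-manual-wall,
params...) -> BinaryMask`` with the scar label, confined to the method's
declared wall search region.  The eight algorithms:

====  =====================================================================
IC    hysteresis thresholding of a joint intensity x distance sigmoid map
MV    region growing seeded/bounded by a 3-component Gaussian mixture
SY    fuzzy-c-means unaries + min-cut over a 4 mm dilated wall
HB    minimal-surface epicardium estimate, then 2-Gaussian EM in the wall
YL    global threshold inside a manually delineated wall
KCL   min-cut with a scar/blood-ratio Gaussian prior in a +-3 mm band
UTA   bimodal-histogram n-SD threshold, optional per-slice offsets
UTB   k-means (k=4) on normalised wall intensities, top cluster = scar
====  =====================================================================

plus the fixed models: ``segment_nsd`` (healthy mean + n SD in a 3 mm
dilated wall) and ``segment_fwhm`` (50% of the maximum of a selected
enhanced region, with region-growing connectivity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import expit
from scipy.stats import norm

from . import graphcut, intensity_models as im, wall_model
from .imaging_io import BinaryMask, Volume3D

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# shared helpers


def _components_touching(candidates: np.ndarray, seeds: np.ndarray,
                         structure=_STRUCT_26) -> np.ndarray:
    """Connected components of ``candidates`` that contain a seed voxel."""
    labels, n = ndimage.label(candidates, structure=structure)
    if n == 0:
        return np.zeros_like(candidates)
    keep = np.unique(labels[seeds & (labels > 0)])
    if keep.size == 0:
        return np.zeros_like(candidates)
    return np.isin(labels, keep)


def remove_small_components(mask: BinaryMask, min_voxels: int = 3,
                            structure=_STRUCT_26) -> BinaryMask:
    """Drop connected components smaller than ``min_voxels``."""
    labels, n = ndimage.label(mask.data, structure=structure)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    keep = np.nonzero(counts >= min_voxels)[0]
    keep = keep[keep > 0]
    return mask.with_data(np.isin(labels, keep))


def _minmax_rescale(values: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1]; constant input maps to zeros."""
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.zeros_like(values, dtype=float)
    return (values - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# IC: hysteresis thresholding of a sigmoid enhancement model


@dataclass(frozen=True)
class SigmoidEnhancementModel:
    """Intensity and distance sigmoids of the probabilistic scar map.

    ``c_i, h_i`` are the centre/width of the intensity sigmoid in
    normalised (SD-above-blood-pool) units; ``c_d, h_d`` of the distance
    sigmoid in mm.  A negative ``h_d`` makes the likelihood decrease
    with distance from the endocardium, as scar should live in the wall.
    """

    c_i: float = 2.0
    h_i: float = 0.5
    c_d: float = 3.0
    h_d: float = -1.0

    def __post_init__(self):
        if self.h_i <= 0:
            raise ValueError("h_i must be positive")
        if self.h_d == 0:
            raise ValueError("h_d must be nonzero")

    def p_intensity(self, normalized):
        return expit((np.asarray(normalized, dtype=float) - self.c_i) / self.h_i)

    def p_distance(self, d_mm):
        return expit((np.asarray(d_mm, dtype=float) - self.c_d) / self.h_d)


def ic_probability_map(vol: Volume3D, endo: BinaryMask,
                       model: SigmoidEnhancementModel) -> Volume3D:
    """Joint map p(x) = p_i(Ihat(x)) * p_d(d(x)) in [0, 1]."""
    stats = im.bloodpool_stats(vol, endo)
    nvol = im.normalize(vol, stats)
    df = wall_model.signed_distance(endo)
    return vol.with_data(model.p_intensity(nvol.data) * model.p_distance(df.data))


def ic_search_region(endo: BinaryMask, model: SigmoidEnhancementModel,
                     t_low: float) -> BinaryMask:
    """Voxels where the distance sigmoid alone still reaches ``t_low``.

    Since p <= p_d everywhere, the segmentation is confined to this
    region by construction.
    """
    df = wall_model.signed_distance(endo)
    logit = np.log(t_low / (1.0 - t_low))
    bound = model.c_d + model.h_d * logit
    if model.h_d < 0:
        sel = df.data <= bound + 1e-9
    else:
        sel = df.data >= bound - 1e-9
    return BinaryMask(sel, endo.spacing, endo.origin, role="region")


def segment_ic(vol: Volume3D, endo: BinaryMask,
               model: SigmoidEnhancementModel | None = None,
               t_high: float = 0.5, t_low: float = 0.25) -> BinaryMask:
    """Hysteresis thresholding of the joint probability map (26-connected).

    Voxels above ``t_high`` are scar; voxels above ``t_low`` join if they
    connect to a strong voxel through above-``t_low`` tissue.
    """
    if not (0.0 <= t_low <= t_high <= 1.0):
        raise ValueError("thresholds must satisfy 0 <= t_low <= t_high <= 1")
    model = model or SigmoidEnhancementModel()
    p = ic_probability_map(vol, endo, model).data
    strong = p >= t_high
    weak = p >= t_low
    return BinaryMask(_components_touching(weak, strong),
                      vol.spacing, vol.origin, role="scar")


# ---------------------------------------------------------------------------
# MV: region growing with 3-component mixture thresholds


def segment_mv(vol: Volume3D, endo: BinaryMask, inner_mm: float = 1.0,
               outer_mm: float = 5.0, seed: int = 0) -> BinaryMask:
    """Mixture-seeded region growing in a band around the endocardium.

    A 3-component Gaussian mixture (blood / neighbouring / LGE by
    ascending mean) is fitted to the LA-region intensities; seeds are
    band voxels above I_s (0.15 mu_B + 0.85 mu_LGE) and growth admits
    26-connected voxels above I_R (the blood/LGE density crossing,
    capped at mu_LGE), confined to the band.
    """
    la_region = wall_model.dilate_mm(endo, outer_mm)
    mix = im.gmm_em_fit(vol.data[la_region.data], 3, seed=seed)
    i_s = im.mv_seed_threshold(mix)
    i_r = im.mv_growth_threshold(mix)
    df = wall_model.signed_distance(endo)
    band = wall_model.band_mask(df, inner_mm, outer_mm).data
    seeds = band & (vol.data > i_s)
    if not seeds.any():
        return BinaryMask(np.zeros(vol.shape, dtype=bool), vol.spacing,
                          vol.origin, role="scar")
    admissible = (band & (vol.data > i_r)) | seeds
    return BinaryMask(_components_touching(admissible, seeds),
                      vol.spacing, vol.origin, role="scar")


# ---------------------------------------------------------------------------
# SY: fuzzy c-means unaries + graph cut in a 4 mm dilated wall


def segment_sy(vol: Volume3D, endo: BinaryMask, lam: float = 0.5,
               beta: float = 5.0, dilation_mm: float = 4.0,
               min_cluster_voxels: int = 3, seed: int = 0,
               connectivity: int = 6,
               include_interior: bool = False) -> BinaryMask:
    """Graph-cut segmentation with fuzzy-membership unaries.

    Fuzzy c-means (C=2, m=2) on the wall intensities provides the unary
    costs (1 - membership); the boundary term penalises intensity
    dissimilarity on min-max rescaled wall intensities (so the fixed
    beta=5 acts on a unit range).  Small clusters are removed afterwards.
    """
    wall = wall_model.wall_shell(endo, dilation_mm, include_interior)
    vals = vol.data[wall.data]
    if vals.size == 0:
        raise ValueError("wall region is empty")
    if float(vals.std(ddof=0)) < 1e-12:
        # uniform wall: no contrast, nothing to label as scar
        return BinaryMask(np.zeros(vol.shape, dtype=bool), vol.spacing,
                          vol.origin, role="scar")
    fcm = im.fuzzy_cmeans(vals, C=2, m=2.0, seed=seed)
    scar_cluster = int(np.argmax(fcm.centers))
    u_scar = fcm.memberships[:, scar_cluster]
    unary = np.stack([u_scar, 1.0 - u_scar], axis=1)  # cost(healthy), cost(scar)
    problem = graphcut.build_problem(
        vol, wall, unary, lam=lam, beta=beta, connectivity=connectivity,
        intensities=_minmax_rescale(vals))
    scar = graphcut.solve_global_min(problem, vol.spacing, vol.origin)
    return remove_small_components(scar, min_cluster_voxels)


# ---------------------------------------------------------------------------
# HB: minimal-surface epicardium + 2-Gaussian EM classification


def hb_wall(vol: Volume3D, endo: BinaryMask, lam: float = 0.5,
            smooth_sigma_mm: float = 1.0,
            max_wall_mm: float = 3.0) -> BinaryMask:
    """Epicardial surface by exact minimisation of the wall energy.

    The energy integrates (1 - lambda) f(x) + lambda (d(x) - w)^2 over
    the epicardial surface, with f = 1 / (1 + |G_sigma * grad I|) small
    on strong edges and w the expected wall thickness.  The discrete
    minimiser is found as a weighted minimal surface: a min-cut through
    the narrow band 0 < d <= 2w whose face weights are the local energy
    density times the face area.  The wall is the region between the
    endocardium and the optimal surface.
    """
    df = wall_model.signed_distance(endo)
    spacing = np.asarray(vol.spacing)
    sigma_vox = smooth_sigma_mm / spacing
    smoothed = ndimage.gaussian_filter(vol.data, sigma=sigma_vox)
    grads = np.gradient(smoothed, *vol.spacing)
    gmag = np.sqrt(sum(g ** 2 for g in grads))
    f = 1.0 / (1.0 + gmag)
    g = (1.0 - lam) * f + lam * (df.data - max_wall_mm) ** 2

    band_mm = 2.0 * max_wall_mm
    band = (df.data > 0) & (df.data <= band_mm + 1e-9)
    inside = endo.data
    outside = ~band & ~inside

    coords, index, pairs, axes = graphcut.grid_adjacency(band, connectivity=6)
    n = coords.shape[0]
    voxel_vol = float(np.prod(spacing))
    face_area = voxel_vol / spacing  # per axis

    g_nodes = g[band]
    if pairs.shape[0]:
        axis_id = np.argmax(np.abs(axes), axis=1)
        w = 0.5 * (g_nodes[pairs[:, 0]] + g_nodes[pairs[:, 1]]) \
            * face_area[axis_id]
    else:
        w = np.empty(0)

    # terminal faces: band voxels abutting the endocardium pay when cut
    # outside; band voxels abutting the far field pay when cut inside
    unary = np.zeros((n, 2))
    for axis in range(3):
        for sign in (-1, 1):
            nbr = coords.copy()
            nbr[:, axis] += sign
            ok = (nbr[:, axis] >= 0) & (nbr[:, axis] < vol.shape[axis])
            nb_inside = np.zeros(n, dtype=bool)
            nb_outside = np.zeros(n, dtype=bool)
            nb_inside[ok] = inside[tuple(nbr[ok].T)]
            nb_outside[ok] = outside[tuple(nbr[ok].T)]
            g_nbr = np.full(n, np.nan)
            g_nbr[ok] = g[tuple(nbr[ok].T)]
            face = face_area[axis]
            sel = nb_inside
            unary[sel, graphcut.HEALTHY] += \
                0.5 * (g_nodes[sel] + g_nbr[sel]) * face
            sel = nb_outside
            unary[sel, graphcut.SCAR] += \
                0.5 * (g_nodes[sel] + g_nbr[sel]) * face

    problem = graphcut.GraphCutProblem(unary, pairs, w, lam=0.5,
                                       node_coords=coords,
                                       grid_shape=vol.shape)
    labels = graphcut.solve_labels(problem)
    wall = np.zeros(vol.shape, dtype=bool)
    wall[tuple(coords[labels == graphcut.SCAR].T)] = True
    if not wall.any():
        warnings.warn("epicardial surface collapsed onto the endocardium; "
                      "wall is empty")
    return BinaryMask(wall, vol.spacing, vol.origin, role="wall")


def segment_hb(vol: Volume3D, endo: BinaryMask, lam: float = 0.5,
               smooth_sigma_mm: float = 1.0, max_wall_mm: float = 3.0,
               seed: int = 0) -> BinaryMask:
    """Wall from the minimal-surface epicardium, scar by 2-Gaussian EM.

    Wall intensities are modelled as a healthy/scar two-component
    mixture; voxels whose posterior favours the higher-mean component
    are labelled scar.
    """
    wall = hb_wall(vol, endo, lam=lam, smooth_sigma_mm=smooth_sigma_mm,
                   max_wall_mm=max_wall_mm)
    empty = BinaryMask(np.zeros(vol.shape, dtype=bool), vol.spacing,
                       vol.origin, role="scar")
    if wall.count == 0:
        return empty
    vals = vol.data[wall.data]
    try:
        mix = im.gmm_em_fit(vals, 2, seed=seed)
    except (im.DegenerateFitError, ValueError):
        warnings.warn("wall intensity mixture degenerate; no scar labelled")
        return empty
    resp = mix.responsibilities(vals)
    scar_comp = mix.index_of("scar")
    out = np.zeros(vol.shape, dtype=bool)
    out[wall.data] = resp.argmax(axis=1) == scar_comp
    return BinaryMask(out, vol.spacing, vol.origin, role="scar")


# ---------------------------------------------------------------------------
# YL: global threshold in a manual wall


def segment_yl(vol: Volume3D, wall_manual: BinaryMask,
               threshold: float) -> BinaryMask:
    """Wall voxels with intensity above a single volume-wide threshold."""
    if wall_manual is None:
        raise ValueError("YL requires a manual wall mask")
    vol.check_same_grid(wall_manual)
    return BinaryMask(wall_manual.data & (vol.data > threshold),
                      vol.spacing, vol.origin, role="scar")


# ---------------------------------------------------------------------------
# KCL: graph cut with a scar/blood-ratio prior


@dataclass(frozen=True)
class ScarPrior:
    """Gaussian prior on the scar-to-mean-blood-pool intensity ratio."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("prior SD must be positive")


def segment_kcl(vol: Volume3D, endo: BinaryMask, prior: ScarPrior,
                lam: float = 0.5, band_mm: float = 3.0,
                k_range=(1, 2, 3, 4, 5), beta: float = 5.0,
                seed: int = 0, connectivity: int = 6) -> BinaryMask:
    """Min-cut with a ratio-Gaussian scar model and a BIC-selected
    healthy mixture, both fitted in the +-3 mm endocardial band.

    The scar unary is the density of I/mu_B under the prior (change of
    variables to intensity units so both unaries share a scale); the
    healthy unary is the mixture density of the band.  Densities become
    costs via -log(max(p, 1e-12)).
    """
    df = wall_model.signed_distance(endo)
    band = wall_model.band_mask(df, band_mm, band_mm)
    stats = im.bloodpool_stats(vol, endo)
    vals = vol.data[band.data]
    healthy_mix = im.gmm_select_k(vals, k_range=k_range, seed=seed)

    p_healthy = healthy_mix.pdf(vals)
    p_scar = norm.pdf(vals / stats.mean, loc=prior.mean,
                      scale=prior.sd) / stats.mean
    unary = np.stack([graphcut.probabilities_to_costs(p_healthy),
                      graphcut.probabilities_to_costs(p_scar)], axis=1)
    problem = graphcut.build_problem(
        vol, band, unary, lam=lam, beta=beta, connectivity=connectivity,
        intensities=_minmax_rescale(vals))
    return graphcut.solve_global_min(problem, vol.spacing, vol.origin)


# ---------------------------------------------------------------------------
# UTA: bimodal-histogram n-SD threshold with per-slice offsets


def segment_uta(vol: Volume3D, wall_manual: BinaryMask, n_sd: float = 3.0,
                slice_offsets=None, slice_axis: int = 2,
                seed: int = 0) -> BinaryMask:
    """Lower-mode mean + n SD threshold in a manual wall.

    ``slice_offsets`` optionally shifts the global threshold per slice
    along ``slice_axis`` (a mapping slice index -> offset), standing in
    for the operator's per-slice adjustment.
    """
    if wall_manual is None:
        raise ValueError("UTA requires a manual wall mask")
    vol.check_same_grid(wall_manual)
    thr = im.bimodal_threshold(vol.data[wall_manual.data], n_sd, seed=seed)
    thresholds = np.full(vol.shape[slice_axis], thr)
    if slice_offsets is not None:
        for k, off in dict(slice_offsets).items():
            thresholds[int(k)] += off
    shape = [1, 1, 1]
    shape[slice_axis] = -1
    out = wall_manual.data & (vol.data > thresholds.reshape(shape))
    return BinaryMask(out, vol.spacing, vol.origin, role="scar")


# ---------------------------------------------------------------------------
# UTB: k-means clustering, top-mean cluster = scar


def segment_utb(vol: Volume3D, wall_manual: BinaryMask, k: int = 4,
                seed: int = 0, blood: BinaryMask | None = None) -> BinaryMask:
    """k-means on (blood-pool-normalised) wall intensities.

    The cluster with the highest mean intensity is the scar cluster.
    Normalisation is affine and therefore does not change the k-means
    partition; the blood mask is accepted for interface completeness.
    """
    if wall_manual is None:
        raise ValueError("UTB requires a manual wall mask")
    vol.check_same_grid(wall_manual)
    vals = vol.data[wall_manual.data]
    if vals.size < k:
        raise ValueError(f"need at least k={k} wall voxels")
    if blood is not None:
        stats = im.bloodpool_stats(vol, blood)
        vals = (vals - stats.mean) / stats.sd
    result = im.kmeans_cluster(vals, k, seed=seed)
    top = int(np.argmax(result.centers))
    out = np.zeros(vol.shape, dtype=bool)
    out[wall_manual.data] = result.labels == top
    return BinaryMask(out, vol.spacing, vol.origin, role="scar")


# ---------------------------------------------------------------------------
# fixed models: n-SD and FWHM


def nsd_threshold(vol: Volume3D, healthy_region: BinaryMask,
                  n: float) -> float:
    """Healthy-region mean + n x population SD."""
    vol.check_same_grid(healthy_region)
    samples = vol.data[healthy_region.data]
    if samples.size < 2:
        raise ValueError("healthy region must contain at least 2 voxels")
    sd = float(samples.std(ddof=0))
    if sd == 0:
        raise im.DegenerateFitError("healthy region has zero variance")
    return float(samples.mean()) + n * sd


def segment_nsd(vol: Volume3D, endo: BinaryMask, healthy_region: BinaryMask,
                n: float = 4.0, wall_mm: float = 3.0,
                include_interior: bool = False) -> BinaryMask:
    """Threshold at healthy-region mean + n SD in the 3 mm dilated wall."""
    thr = nsd_threshold(vol, healthy_region, n)
    wall = wall_model.wall_shell(endo, wall_mm, include_interior)
    return BinaryMask(wall.data & (vol.data > thr), vol.spacing, vol.origin,
                      role="scar")


def fwhm_threshold(vol: Volume3D, enhanced_region: BinaryMask,
                   fraction: float = 0.5) -> float:
    """``fraction`` x the maximum intensity of the enhanced region."""
    vol.check_same_grid(enhanced_region)
    if enhanced_region.count == 0:
        raise ValueError("enhanced region is empty")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    return fraction * float(vol.data[enhanced_region.data].max())


def segment_fwhm(vol: Volume3D, endo: BinaryMask,
                 enhanced_region: BinaryMask, fraction: float = 0.5,
                 wall_mm: float = 3.0,
                 include_interior: bool = False) -> BinaryMask:
    """Full-width-at-half-maximum threshold with connectivity.

    The threshold is ``fraction`` x the maximum intensity of the
    observer-selected enhanced region (re-adjustable to 0.6/0.7); output
    voxels must exceed it inside the dilated wall and be 26-connected to
    the enhanced region through above-threshold tissue.
    """
    thr = fwhm_threshold(vol, enhanced_region, fraction)
    wall = wall_model.wall_shell(endo, wall_mm, include_interior)
    candidates = wall.data & (vol.data >= thr)
    seeds = candidates & enhanced_region.data
    if not seeds.any():
        # the maximal voxel may sit just outside the dilated wall; seed
        # from any above-threshold voxel adjacent to the region instead
        near = ndimage.binary_dilation(enhanced_region.data, _STRUCT_26)
        seeds = candidates & near
    return BinaryMask(_components_touching(candidates, seeds),
                      vol.spacing, vol.origin, role="scar")


# ---------------------------------------------------------------------------
# method registry (used by the benchmark harness and confinement checks)


@dataclass(frozen=True)
class MethodSpec:
    """How the harness drives a method: inputs it needs and its region."""

    name: str
    needs: tuple[str, ...]   # subset of (endo, wall, healthy, enhanced, prior, threshold)
    stochastic: bool


METHODS = {
    "ic": MethodSpec("ic", ("endo",), False),
    "mv": MethodSpec("mv", ("endo",), True),
    "sy": MethodSpec("sy", ("endo",), True),
    "hb": MethodSpec("hb", ("endo",), True),
    "yl": MethodSpec("yl", ("wall", "threshold"), False),
    "kcl": MethodSpec("kcl", ("endo", "prior"), True),
    "uta": MethodSpec("uta", ("wall",), True),
    "utb": MethodSpec("utb", ("wall",), True),
    "nsd": MethodSpec("nsd", ("endo", "healthy"), False),
    "fwhm": MethodSpec("fwhm", ("endo", "enhanced"), False),
}

#: methods whose search region comes from a manual wall mask
MANUAL_WALL_METHODS = ("yl", "uta", "utb")


def declared_region(method: str, vol: Volume3D, endo: BinaryMask | None = None,
                    wall_manual: BinaryMask | None = None,
                    params: dict | None = None) -> BinaryMask:
    """The wall search region a method's output is confined to."""
    p = dict(params or {})
    if method in MANUAL_WALL_METHODS:
        if wall_manual is None:
            raise ValueError(f"{method} region requires the manual wall")
        return wall_manual
    if endo is None:
        raise ValueError(f"{method} region requires the endocardial mask")
    if method == "ic":
        model = p.get("model") or SigmoidEnhancementModel()
        return ic_search_region(endo, model, p.get("t_low", 0.25))
    if method == "mv":
        df = wall_model.signed_distance(endo)
        return wall_model.band_mask(df, p.get("inner_mm", 1.0),
                                    p.get("outer_mm", 5.0))
    if method == "sy":
        return wall_model.wall_shell(endo, p.get("dilation_mm", 4.0),
                                     p.get("include_interior", False))
    if method == "hb":
        return wall_model.wall_shell(endo, 2.0 * p.get("max_wall_mm", 3.0))
    if method == "kcl":
        df = wall_model.signed_distance(endo)
        b = p.get("band_mm", 3.0)
        return wall_model.band_mask(df, b, b)
    if method in ("nsd", "fwhm"):
        return wall_model.wall_shell(endo, p.get("wall_mm", 3.0),
                                     p.get("include_interior", False))
    raise ValueError(f"unknown method {method!r}")


def run_method(method: str, vol: Volume3D, inputs: dict,
               params: dict | None = None, seed: int = 0) -> BinaryMask:
    """Uniform dispatch used by the CLI and the benchmark harness.

    ``inputs`` may provide ``endo``, ``wall``, ``healthy``, ``enhanced``
    masks, a ``prior`` (:class:`ScarPrior`) and a ``threshold`` scalar.
    """
    p = dict(params or {})
    if method == "ic":
        return segment_ic(vol, inputs["endo"], p.get("model"),
                          p.get("t_high", 0.5), p.get("t_low", 0.25))
    if method == "mv":
        return segment_mv(vol, inputs["endo"], p.get("inner_mm", 1.0),
                          p.get("outer_mm", 5.0), seed=seed)
    if method == "sy":
        return segment_sy(vol, inputs["endo"], p.get("lam", 0.5),
                          p.get("beta", 5.0), p.get("dilation_mm", 4.0),
                          p.get("min_cluster_voxels", 3), seed=seed)
    if method == "hb":
        return segment_hb(vol, inputs["endo"], p.get("lam", 0.5),
                          p.get("smooth_sigma_mm", 1.0),
                          p.get("max_wall_mm", 3.0), seed=seed)
    if method == "yl":
        return segment_yl(vol, inputs["wall"], inputs["threshold"])
    if method == "kcl":
        return segment_kcl(vol, inputs["endo"], inputs["prior"],
                           p.get("lam", 0.5), p.get("band_mm", 3.0),
                           p.get("k_range", (1, 2, 3, 4, 5)),
                           p.get("beta", 5.0), seed=seed)
    if method == "uta":
        return segment_uta(vol, inputs["wall"], p.get("n_sd", 3.0),
                           p.get("slice_offsets"), p.get("slice_axis", 2),
                           seed=seed)
    if method == "utb":
        return segment_utb(vol, inputs["wall"], p.get("k", 4), seed=seed,
                           blood=inputs.get("endo"))
    if method == "nsd":
        return segment_nsd(vol, inputs["endo"], inputs["healthy"],
                           p.get("n", 4.0), p.get("wall_mm", 3.0),
                           p.get("include_interior", False))
    if method == "fwhm":
        return segment_fwhm(vol, inputs["endo"], inputs["enhanced"],
                            p.get("fraction", 0.5), p.get("wall_mm", 3.0),
                            p.get("include_interior", False))
    raise ValueError(f"unknown method {method!r}")
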
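"""Statistical intensity machinery shared by the segmentation algorithms.

Blood-pool normalisation, one-dimensional Gaussian-mixture EM with BIC
model selection, fuzzy c-means, k-means, the bimodal-histogram threshold
of the Utah method, and the seed/growth thresholds of the Mevis
region-growing method.

Conventions used throughout:

* standard deviations use the population (N) denominator — n-SD
  thresholds depend on this choice;
* mixture components are tagged by ascending mean (``healthy < scar``
  for K=2, ``blood < neighbouring < LGE`` for K=3);
* all fits are deterministic given a seed, and EM/FCM record their
  objective trajectory so monotonicity can be asserted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .imaging_io import BinaryMask, Volume3D


class DegenerateFitError(RuntimeError):
    """A fit collapsed (zero variance / duplicate centres) and cannot proceed."""


# ---------------------------------------------------------------------------
# blood-pool statistics and normalisation


@dataclass(frozen=True)
class BloodPoolStats:
    """Mean and SD of the LA blood-pool cavity intensities."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def bloodpool_stats(vol: Volume3D, blood: BinaryMask) -> BloodPoolStats:
    """Sample mean and population SD of intensities under the blood mask."""
    vol.check_same_grid(blood)
    samples = vol.data[blood.data]
    if samples.size < 2:
        raise ValueError("blood-pool mask must contain at least 2 voxels")
    mu = float(samples.mean())
    sd = float(samples.std(ddof=0))
    if sd == 0:
        raise DegenerateFitError("blood-pool region has zero variance")
    return BloodPoolStats(mu, sd)


def normalize(vol: Volume3D, stats: BloodPoolStats) -> Volume3D:
    """Express intensities in SD-above-blood-pool units: (I - mu_B) / sigma_B."""
    if stats.sd == 0:
        raise DegenerateFitError("cannot normalize with zero blood-pool SD")
    return vol.with_data((vol.data - stats.mean) / stats.sd)


# ---------------------------------------------------------------------------
# Gaussian mixtures (1-D EM)

_DEFAULT_TAGS = {
    1: ("all",),
    2: ("healthy", "scar"),
    3: ("blood", "neighbouring", "LGE"),
}


@dataclass(frozen=True)
class GaussianMixture:
    """Weights/means/SDs of K Gaussian components with field-name tags.

    Components are stored in ascending order of mean.  ``log_likelihoods``
    is the per-iteration trajectory of the EM fit that produced the model
    (empty for models built directly).
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    tags: tuple[str, ...]
    log_likelihoods: tuple[float, ...] = ()

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        if not (w.shape == m.shape == s.shape) or w.ndim != 1:
            raise ValueError("weights/means/sds must be 1-D and equally sized")
        if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ValueError("weights must be non-negative and sum to 1")
        if (s <= 0).any():
            raise DegenerateFitError("all component SDs must be positive")
        if len(self.tags) != w.size:
            raise ValueError("one tag per component required")
        for a in ("weights", "means", "sds"):
            arr = {"weights": w, "means": m, "sds": s}[a]
            arr.flags.writeable = False
            object.__setattr__(self, a, arr)
        object.__setattr__(self, "tags", tuple(self.tags))

    @property
    def n_components(self) -> int:
        return int(self.weights.size)

    def component_logpdf(self, x) -> np.ndarray:
        """(n, K) matrix of weighted per-component log densities."""
        x = np.atleast_1d(np.asarray(x, dtype=float))[:, None]
        return (
            np.log(np.maximum(self.weights, 1e-300))
            - 0.5 * np.log(2.0 * np.pi * self.sds ** 2)
            - 0.5 * ((x - self.means) / self.sds) ** 2
        )

    def pdf(self, x) -> np.ndarray:
        return np.exp(logsumexp(self.component_logpdf(x), axis=1))

    def log_likelihood(self, samples) -> float:
        return float(logsumexp(self.component_logpdf(samples), axis=1).sum())

    def responsibilities(self, x) -> np.ndarray:
        lp = self.component_logpdf(x)
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))

    def index_of(self, tag: str) -> int:
        try:
            return self.tags.index(tag)
        except ValueError:
            raise KeyError(f"mixture has no component tagged {tag!r}") from None

    def mean_of(self, tag: str) -> float:
        return float(self.means[self.index_of(tag)])

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "tags": list(self.tags),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GaussianMixture":
        d = json.loads(text)
        return cls(np.array(d["weights"]), np.array(d["means"]),
                   np.array(d["sds"]), tuple(d["tags"]))


def _kmeanspp_centers(x: np.ndarray, k: int, rng: np.random.Generator):
    """k-means++ seeding on scalars (deterministic under the generator)."""
    centers = [x[rng.integers(x.size)]]
    for _ in range(1, k):
        d2 = np.min((x[:, None] - np.array(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:
            centers.append(x[rng.integers(x.size)])
            continue
        centers.append(x[rng.choice(x.size, p=d2 / total)])
    return np.sort(np.array(centers, dtype=float))


def gmm_em_fit(samples, K: int, seed: int = 0, tol: float = 1e-6,
               max_iter: int = 500, tags=None) -> GaussianMixture:
    """Fit a K-component 1-D Gaussian mixture by EM.

    The log-likelihood is recorded each iteration and is non-decreasing
    (the EM guarantee); component collapse (SD -> 0) raises
    :class:`DegenerateFitError` rather than being clipped silently.
    Components are tagged by ascending mean.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if K < 1:
        raise ValueError("K must be >= 1")
    if x.size < 10 * K:
        raise ValueError(f"need at least {10 * K} samples for K={K}")
    scale = float(x.std(ddof=0))
    if scale == 0:
        raise DegenerateFitError("samples have zero variance")
    rng = np.random.default_rng(seed)

    means = _kmeanspp_centers(x, K, rng)
    sds = np.full(K, max(scale / max(K, 1), 1e-3 * scale))
    weights = np.full(K, 1.0 / K)
    lls: list[float] = []
    sd_floor = 1e-8 * scale

    for _ in range(max_iter):
        mix = GaussianMixture(weights, means, sds,
                              tuple(f"c{i}" for i in range(K)))
        lp = mix.component_logpdf(x)
        ll = float(logsumexp(lp, axis=1).sum())
        lls.append(ll)
        resp = np.exp(lp - logsumexp(lp, axis=1, keepdims=True))
        nk = resp.sum(axis=0)
        if (nk < 1e-10).any():
            raise DegenerateFitError("a mixture component lost all support")
        weights = nk / x.size
        means_new = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means_new) ** 2).sum(axis=0) / nk
        sds_new = np.sqrt(var)
        if (sds_new < sd_floor).any():
            raise DegenerateFitError("mixture component collapsed (sigma -> 0)")
        order = np.argsort(means_new)
        means, sds, weights = means_new[order], sds_new[order], weights[order]
        if len(lls) > 1 and abs(lls[-1] - lls[-2]) <= tol * abs(lls[-2]):
            break

    if tags is None:
        tags = _DEFAULT_TAGS.get(K, tuple(f"component_{i}" for i in range(K)))
    if np.unique(means).size < K:
        warnings.warn("mixture has tied component means; tag order arbitrary")
    return GaussianMixture(weights, means, sds, tuple(tags), tuple(lls))


def gmm_select_k(samples, k_range=(1, 2, 3, 4, 5), seed: int = 0,
                 tol: float = 1e-6, max_iter: int = 500) -> GaussianMixture:
    """Fit over candidate K and return the BIC-minimising mixture.

    BIC = -2 log L + (3K - 1) log n.  Candidate fits that degenerate are
    skipped; if all fail the error propagates.
    """
    x = np.asarray(samples, dtype=float).ravel()
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1 or ks[-1] > 5:
        raise ValueError("k_range must lie within [1, 5]")
    best, best_bic, last_err = None, np.inf, None
    for k in ks:
        try:
            fit = gmm_em_fit(x, k, seed=seed, tol=tol, max_iter=max_iter,
                             tags=tuple(f"component_{i}" for i in range(k)))
        except (DegenerateFitError, ValueError) as err:
            last_err = err
            continue
        bic = -2.0 * fit.log_likelihoods[-1] + (3 * k - 1) * np.log(x.size)
        if bic < best_bic:
            best, best_bic = fit, bic
    if best is None:
        raise DegenerateFitError(f"no candidate K admitted a fit: {last_err}")
    return best


# ---------------------------------------------------------------------------
# Mevis seed / growth thresholds


def mv_seed_threshold(mix: GaussianMixture) -> float:
    """Seed cut-off I_s = 0.15 mu_B + 0.85 mu_LGE."""
    return 0.15 * mix.mean_of("blood") + 0.85 * mix.mean_of("LGE")


def mv_growth_threshold(mix: GaussianMixture, tol: float = 1e-6) -> float:
    """Region-growing cut-off I_R = min(mu_LGE, I_t).

    I_t is the intensity between the blood and LGE means where the
    weighted blood and LGE densities cross.  If the two weighted pdfs do
    not cross between the means a warning is issued and mu_LGE is used.
    """
    ib, il = mix.index_of("blood"), mix.index_of("LGE")
    mu_b, mu_l = mix.means[ib], mix.means[il]
    if not mu_b < mu_l:
        raise ValueError("requires mu_blood < mu_LGE")

    def diff(x):
        lp = mix.component_logpdf(x)
        return (lp[:, ib] - lp[:, il])[0] if np.ndim(x) == 0 else lp[:, ib] - lp[:, il]

    grid = np.linspace(mu_b, mu_l, 512)
    vals = diff(grid)
    sign = np.sign(vals)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if crossings.size == 0:
        warnings.warn("blood and LGE mixtures do not cross between the means; "
                      "falling back to mu_LGE")
        return float(mu_l)
    i = crossings[-1]  # crossing nearest the LGE mean
    it = optimize.brentq(lambda x: float(diff(np.array([x]))[0]),
                         grid[i], grid[i + 1], xtol=tol)
    return float(min(mu_l, it))


# ---------------------------------------------------------------------------
# clustering


@dataclass(frozen=True)
class ClusterResult:
    """Cluster centres, hard labels, and (for FCM) fuzzy memberships."""

    centers: np.ndarray
    labels: np.ndarray
    memberships: np.ndarray | None = None
    objective: tuple[float, ...] = ()

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        l = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "labels", l)
        if self.memberships is not None:
            u = np.asarray(self.memberships, dtype=float)
            if not np.allclose(u.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("fuzzy memberships must row-sum to 1")
            if (u < -1e-12).any() or (u > 1 + 1e-12).any():
                raise ValueError("fuzzy memberships must lie in [0, 1]")
            if not np.array_equal(u.argmax(axis=1), l):
                raise ValueError("hard labels must be the membership argmax")
            object.__setattr__(self, "memberships", u)


def fuzzy_cmeans(samples, C: int = 2, m: float = 2.0, seed: int = 0,
                 tol: float = 1e-8, max_iter: int = 300) -> ClusterResult:
    """Standard fuzzy c-means on scalar samples.

    The FCM objective sum_ik u_ik^m d_ik^2 is non-increasing across
    iterations (recorded in ``objective``).  Duplicate centre collapse
    raises :class:`DegenerateFitError`.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if C < 2:
        raise ValueError("C must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if x.size < C:
        raise ValueError("need at least C samples")
    scale = float(x.std(ddof=0))
    if scale == 0:
        raise DegenerateFitError("samples have zero variance")
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_centers(x, C, rng)
    power = 2.0 / (m - 1.0)
    objective: list[float] = []
    u = None
    for _ in range(max_iter):
        d2 = (x[:, None] - centers[None, :]) ** 2
        d2 = np.maximum(d2, 1e-300)
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        # exact-hit samples get membership 1 in their cluster
        hits = d2.min(axis=1) < (1e-12 * scale) ** 2
        if hits.any():
            u[hits] = 0.0
            u[hits, d2[hits].argmin(axis=1)] = 1.0
        um = u ** m
        objective.append(float((um * d2).sum()))
        denom = um.sum(axis=0)
        if (denom <= 0).any():
            raise DegenerateFitError("FCM cluster lost all membership")
        new_centers = (um * x[:, None]).sum(axis=0) / denom
        if np.min(np.diff(np.sort(new_centers))) < 1e-12 * max(scale, 1.0):
            raise DegenerateFitError("FCM centres collapsed onto each other")
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol * max(scale, 1.0):
            break
    order = np.argsort(centers)
    u = u[:, order]
    u = u / u.sum(axis=1, keepdims=True)
    return ClusterResult(centers[order], u.argmax(axis=1), u, tuple(objective))


def kmeans_cluster(samples, k: int, seed: int = 0) -> ClusterResult:
    """Lloyd k-means on scalar samples (deterministic under the seed).

    Centres are returned in ascending order.  Empty-cluster events are
    handled by the underlying solver's re-seeding strategy.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < k:
        raise ValueError("need at least k samples")
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed)).fit(x[:, None])
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    remap = np.empty_like(order)
    remap[order] = np.arange(k)
    return ClusterResult(centers[order], remap[km.labels_])


# ---------------------------------------------------------------------------
# bimodal-histogram threshold (Utah A)


def bimodal_threshold(samples, n_sd: float, seed: int = 0) -> float:
    """Lower-mode mean + n_sd x lower-mode SD of a bimodal wall histogram.

    The two modes (non-enhanced and enhanced wall) are estimated with a
    2-component EM fit; a degenerate (effectively unimodal) sample raises
    :class:`DegenerateFitError`.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 20:
        raise ValueError("need at least 20 samples")
    if float(x.std(ddof=0)) == 0:
        raise DegenerateFitError("all samples identical; histogram is degenerate")
    mix = gmm_em_fit(x, 2, seed=seed, tags=("lower", "upper"))
    lo = mix.index_of("lower")
    return float(mix.means[lo] + n_sd * mix.sds[lo])
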
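"""Exact binary energy minimisation over voxel graphs.

The energy is the standard two-label MRF functional

    E(L) = lambda * sum_x R_x(L_x)
         + (1 - lambda) * sum_{(x,y) in N, L_x != L_y} B_xy

with non-negative unary costs R and non-negative boundary weights

    B_xy = exp(-beta |I_x - I_y|^2) / d(x, y)

where d(x, y) is the physical (mm) distance between voxel centres.  The
pairwise term penalises label discontinuities only (Potts form), which
makes the energy submodular, so the global optimum is found exactly by a
minimum s-t cut.  Ties are broken toward the healthy label.

The solver scales capacities to 32-bit integers (sized so both every
capacity and the total flow fit) and runs the C max-flow in
:mod:`scipy.sparse.csgraph`; the partition is recovered by a BFS of the
residual graph from the source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .imaging_io import BinaryMask, Volume3D

HEALTHY, SCAR = 0, 1

_OFFSETS_6 = np.array([(1, 0, 0), (0, 1, 0), (0, 0, 1)])
_OFFSETS_26 = np.array(
    [(i, j, k)
     for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
     if (i, j, k) > (0, 0, 0)]  # 13 half-space offsets
)


def pairwise_weight(I_x, I_y, d_xy, beta):
    """Boundary weight exp(-beta |I_x - I_y|^2) / d_xy (vectorised)."""
    d = np.asarray(d_xy, dtype=float)
    if np.any(d <= 0):
        raise ValueError("voxel-centre distance must be positive")
    if np.any(np.asarray(beta) < 0):
        raise ValueError("beta must be non-negative")
    diff = np.asarray(I_x, dtype=float) - np.asarray(I_y, dtype=float)
    return np.exp(-beta * diff ** 2) / d


@dataclass(frozen=True)
class GraphCutProblem:
    """A submodular two-label problem on the voxels of a wall mask.

    ``pairs`` holds index pairs into the node list; ``pair_weights`` are
    the B_xy >= 0; ``unary`` is an (n, 2) array of R_x(L) >= 0 costs.
    ``node_index`` maps nodes back to voxel coordinates of the source
    grid (may be None for abstract problems).
    """

    unary: np.ndarray
    pairs: np.ndarray
    pair_weights: np.ndarray
    lam: float
    node_coords: np.ndarray | None = None
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self):
        u = np.asarray(self.unary, dtype=float)
        if u.ndim != 2 or u.shape[1] != 2:
            raise ValueError("unary must be (n, 2)")
        if not np.isfinite(u).all() or (u < 0).any():
            raise ValueError("unary costs must be finite and non-negative")
        p = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        w = np.asarray(self.pair_weights, dtype=float).ravel()
        if p.shape[0] != w.size:
            raise ValueError("one weight per pair required")
        if not np.isfinite(w).all() or (w < 0).any():
            raise ValueError("pairwise weights must be finite and non-negative")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        for name, arr in (("unary", u), ("pairs", p), ("pair_weights", w)):
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)

    @property
    def n_nodes(self) -> int:
        return int(self.unary.shape[0])


def probabilities_to_costs(p, floor: float = 1e-12) -> np.ndarray:
    """Convert probabilities/densities to min-cut unary costs: -log max(p, floor)."""
    return -np.log(np.maximum(np.asarray(p, dtype=float), floor))


def grid_adjacency(mask_data: np.ndarray, connectivity: int = 6):
    """Voxel coordinates, index grid and adjacent index pairs of a mask.

    Returns ``(coords, index, pairs, axes)`` where ``pairs`` is (m, 2)
    into the node list and ``axes`` is the (m, 3) integer offset of each
    pair (useful for physical distances / face areas).
    """
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    coords = np.argwhere(mask_data)
    n = coords.shape[0]
    index = -np.ones(mask_data.shape, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(n)
    offsets = _OFFSETS_6 if connectivity == 6 else _OFFSETS_26
    shape = np.asarray(mask_data.shape)
    pair_list, axis_list = [], []
    for off in offsets:
        lo = np.maximum(0, -off)
        hi = shape - np.maximum(0, off)
        src = index[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        dst = index[lo[0] + off[0]:hi[0] + off[0],
                    lo[1] + off[1]:hi[1] + off[1],
                    lo[2] + off[2]:hi[2] + off[2]]
        ok = (src >= 0) & (dst >= 0)
        if not ok.any():
            continue
        pair_list.append(np.stack([src[ok].ravel(), dst[ok].ravel()], axis=1))
        axis_list.append(np.broadcast_to(off, (int(ok.sum()), 3)))
    if pair_list:
        return (coords, index, np.concatenate(pair_list),
                np.concatenate(axis_list))
    return (coords, index, np.empty((0, 2), dtype=np.int64),
            np.empty((0, 3), dtype=np.int64))


def build_problem(vol: Volume3D, wall: BinaryMask, unary_model,
                  lam: float = 0.5, beta: float = 5.0,
                  connectivity: int = 6,
                  intensities: np.ndarray | None = None) -> GraphCutProblem:
    """Assemble the voxel graph of a wall region.

    ``unary_model`` is either an (n, 2) array of per-node label costs or
    a callable mapping the n wall-voxel intensities to such an array.
    ``intensities`` optionally overrides the values used in the boundary
    term (e.g. rescaled intensities) without changing the unaries.
    Pairs connect wall voxels adjacent under 6- or 26-connectivity, with
    distances in physical mm.
    """
    vol.check_same_grid(wall)
    if not wall.data.any():
        raise ValueError("wall mask is empty")
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")

    coords, _, pairs, axes = grid_adjacency(wall.data, connectivity)
    n = coords.shape[0]

    vals = vol.data[wall.data]
    if callable(unary_model):
        unary = np.asarray(unary_model(vals), dtype=float)
    else:
        unary = np.asarray(unary_model, dtype=float)
    if unary.shape != (n, 2) or not np.isfinite(unary).all():
        raise ValueError("unary model must yield finite (n, 2) costs for "
                         "every wall voxel")

    pair_vals = vals if intensities is None else np.asarray(intensities).ravel()
    if pairs.shape[0]:
        dists = np.linalg.norm(axes * np.asarray(vol.spacing), axis=1)
        weights = pairwise_weight(pair_vals[pairs[:, 0]],
                                  pair_vals[pairs[:, 1]], dists, beta)
    else:
        weights = np.empty(0)
    return GraphCutProblem(unary, pairs, weights, lam,
                           node_coords=coords, grid_shape=wall.shape)


def energy_of_labeling(problem: GraphCutProblem, labels) -> float:
    """Evaluate E(L) exactly for a complete labelling."""
    L = np.asarray(labels, dtype=np.int64).ravel()
    if L.size != problem.n_nodes:
        raise ValueError("labelling must cover all nodes")
    data = problem.lam * problem.unary[np.arange(L.size), L].sum()
    if problem.pairs.shape[0]:
        cut = L[problem.pairs[:, 0]] != L[problem.pairs[:, 1]]
        data += (1.0 - problem.lam) * problem.pair_weights[cut].sum()
    return float(data)


def solve_labels(problem: GraphCutProblem) -> np.ndarray:
    """Globally optimal labelling by minimum s-t cut (ties -> healthy)."""
    n = problem.n_nodes
    lam = problem.lam
    s, t = n, n + 1

    cap_s = lam * problem.unary[:, HEALTHY]  # cut when node is sink-side
    cap_t = lam * problem.unary[:, SCAR]     # cut when node is source-side
    pw = (1.0 - lam) * problem.pair_weights

    max_cap = max(cap_s.max(initial=0.0), cap_t.max(initial=0.0),
                  pw.max(initial=0.0))
    if max_cap == 0:
        return np.zeros(n, dtype=np.int64)
    # the max-flow solver uses 32-bit capacities: every capacity and the
    # total flow (bounded by the smaller terminal-capacity sum) must fit
    flow_bound = min(cap_s.sum() + pw.sum(), cap_t.sum() + pw.sum())
    scale = (2 ** 30) / max(max_cap, flow_bound)

    rows, cols, caps = [], [], []

    def add(u, v, c):
        rows.append(u)
        cols.append(v)
        caps.append(c)

    idx = np.arange(n)
    for u, v, c in ((np.full(n, s), idx, cap_s), (idx, np.full(n, t), cap_t)):
        keep = c > 0
        rows.extend(u[keep])
        cols.extend(v[keep])
        caps.extend(np.round(c[keep] * scale).astype(np.int32))
    if pw.size:
        keep = pw > 0
        a, b = problem.pairs[keep, 0], problem.pairs[keep, 1]
        w = np.round(pw[keep] * scale).astype(np.int32)
        rows.extend(np.concatenate([a, b]))
        cols.extend(np.concatenate([b, a]))
        caps.extend(np.concatenate([w, w]))

    graph = sparse.csr_matrix(
        (np.asarray(caps, dtype=np.int32),
         (np.asarray(rows, dtype=np.int64), np.asarray(cols, dtype=np.int64))),
        shape=(n + 2, n + 2),
    )
    graph.sum_duplicates()
    result = maximum_flow(graph, s, t)
    residual = graph - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reachable = breadth_first_order(residual, s, directed=True,
                                    return_predecessors=False)
    labels = np.zeros(n, dtype=np.int64)
    reachable = reachable[reachable < n]
    labels[reachable] = SCAR
    return labels


def solve_global_min(problem: GraphCutProblem,
                     spacing=None, origin=(0.0, 0.0, 0.0)) -> BinaryMask:
    """Solve and return the scar label as a mask on the problem's grid."""
    if problem.node_coords is None or problem.grid_shape is None:
        raise ValueError("problem carries no grid; use solve_labels")
    labels = solve_labels(problem)
    out = np.zeros(problem.grid_shape, dtype=bool)
    scar_coords = problem.node_coords[labels == SCAR]
    out[tuple(scar_coords.T)] = True
    if spacing is None:
        spacing = (1.0, 1.0, 1.0)
    return BinaryMask(out, spacing, origin, role="scar")
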
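"""Quantification of simulated morphologies.

Implements the per-cell energy, the local-minima (fold) count used for
organoid folding, the tube semi-axes used for convergent-extension
tubes, a nested-shell counter, and a fold depth/extent measurement.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .interactions import NeighborGraph, system_gradients
from .state import CellState, ModelConfig


def energy_per_cell(state: CellState, graph: NeighborGraph,
                    config: ModelConfig) -> np.ndarray:
    """Potential energy of each cell: the sum of pair potentials over
    its graph neighbors (each pair contributes to both cells)."""
    _, _, _, energy = system_gradients(
        state.positions, state.ab_polarity, state.pcp, state.lambdas,
        graph, config, pcp_in_plane=state.pcp_in_plane_mask)
    return energy


def count_local_minima(state: CellState, graph: NeighborGraph) -> int:
    """Number of fold bottoms: cells with no neighbor strictly closer to
    the center of mass than themselves whose average angle between AB
    polarity and the displacement vectors to their neighbors is below
    pi/2.  Cells without neighbors are excluded from the count.
    """
    if state.n_cells < 2:
        raise ValueError("need at least 2 cells")
    pos = state.positions
    com = pos.mean(axis=0)
    radial = np.linalg.norm(pos - com, axis=1)
    adj = graph.adjacency_lists()
    return len(_local_minima_indices(state, graph, radial, adj))


def tube_axes(state: CellState,
              opposite_threshold: float = -0.9) -> tuple[float, float]:
    """Semi-major and semi-minor axes of a tube-like shell.

    Cells on opposite walls of a closed epithelium have anti-parallel AB
    polarities, so the tube half-length (half-width) is approximated by
    half the maximum (minimum) distance over all cell pairs whose AB
    polarities satisfy ``p_i . p_j < opposite_threshold``.
    """
    p = state.ab_polarity
    dots = p @ p.T
    iu = np.triu_indices(state.n_cells, k=1)
    mask = dots[iu] < opposite_threshold
    if not mask.any():
        raise ValueError(
            "no cell pair with opposite AB polarity; relax "
            "opposite_threshold (e.g. -0.8) or check the morphology")
    diff = state.positions[iu[0][mask]] - state.positions[iu[1][mask]]
    d = np.linalg.norm(diff, axis=1)
    return float(d.max() / 2.0), float(d.min() / 2.0)


def _restricted_adjacency(state: CellState, graph: NeighborGraph,
                          max_edge_len: float):
    e = graph.edges
    if e.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    d = np.linalg.norm(state.positions[e[:, 0]] - state.positions[e[:, 1]],
                       axis=1)
    return e[d < max_edge_len]


def count_shells(state: CellState, graph: NeighborGraph,
                 max_edge_len: float = 3.0) -> int:
    """Connected components of the neighbor graph restricted to short
    edges (< ``max_edge_len`` cell radii), separating nested shells that
    the line-of-sight rule may still connect across a gap."""
    e = _restricted_adjacency(state, graph, max_edge_len)
    n = state.n_cells
    m = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    ncomp, _ = connected_components(m, directed=False)
    return int(ncomp)


def fold_geometry(state: CellState, graph: NeighborGraph,
                  hops: int = 5) -> tuple[float, float]:
    """Mean depth and mean lateral extent of folds.

    For every local-minimum cell, depth is the difference between the
    largest radial distance within ``hops`` graph steps and the cell's
    own radial distance.  Extent is the graph-geodesic diameter of the
    connected patch of below-median-radial-distance cells containing the
    cell.  Raises if the state has no folds.
    """
    n = state.n_cells
    pos = state.positions
    com = pos.mean(axis=0)
    radial = np.linalg.norm(pos - com, axis=1)
    adj = graph.adjacency_lists()
    minima = _local_minima_indices(state, graph, radial, adj)
    if not minima:
        raise ValueError("no folds (no local minima) in this state")
    e = graph.edges
    m = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    hop = shortest_path(m, directed=False, unweighted=True)

    depths = [float(radial[hop[i] <= hops].max() - radial[i])
              for i in minima]

    below = radial < np.median(radial)
    sub = np.array([(a, b) for a, b in e if below[a] and below[b]],
                   dtype=np.int64).reshape(-1, 2)
    subm = coo_matrix((np.ones(len(sub)), (sub[:, 0], sub[:, 1])),
                      shape=(n, n))
    _, labels = connected_components(subm, directed=False)
    hop_sub = shortest_path(subm, directed=False, unweighted=True)
    extents = []
    for i in minima:
        members = np.flatnonzero(below & (labels == labels[i]))
        if len(members) < 2:
            extents.append(0.0)
            continue
        d = hop_sub[np.ix_(members, members)]
        extents.append(float(d[np.isfinite(d)].max()))
    return float(np.mean(depths)), float(np.mean(extents))


def _local_minima_indices(state, graph, radial, adj) -> list[int]:
    out = []
    for i in range(state.n_cells):
        nbrs = adj[i]
        if not nbrs:
            continue
        if (radial[nbrs] < radial[i]).any():
            continue
        disp = state.positions[nbrs] - state.positions[i]
        disp /= np.linalg.norm(disp, axis=1, keepdims=True)
        ang = np.arccos(np.clip(disp @ state.ab_polarity[i], -1.0, 1.0))
        if ang.mean() < np.pi / 2:
            out.append(i)
    return out
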
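"""Pair interactions between polarized point-particle cells.

Cells are point particles that interact with a short-range repulsive /
longer-range attractive pair potential,

    V(r) = exp(-r^m) - S * exp(-(r/beta)^m),    m in {1, 4}

where ``r`` is the centre-centre distance in units of the cell radius,
``beta > 1`` sets how much longer-ranged the attraction is than the
repulsion, and ``S`` is a polarity-dependent attraction factor.  ``S``
couples the relative orientation of each cell's apical-basal (AB)
polarity ``p`` and planar cell polarity (PCP) ``q`` to the displacement
direction:

    S  = l1*S1 + l2*S2 + l3*S3,     l1 + l2 + l3 = 1
    S1 = (p_i x r_hat) . (p_j x r_hat)
    S2 = (p_i x q_i)   . (p_j x q_j)
    S3 = (q_i x r_hat) . (q_j x r_hat)

Neighborhoods follow a "line of sight" rule: two cells interact only if
the midpoint of their connecting segment is not claimed by any third
cell's Voronoi region (no third cell lies within half the pair distance
of the midpoint).

This module provides the scalar coupling factors, the pair potential and
its analytic gradients with respect to position and both polarity
vectors, the neighbor search, and vectorized kernels used by the
integrator.  Gradients with respect to a polarity are tangential
(projected onto the plane orthogonal to the unit polarity), which is the
derivative of the potential through the normalized vector evaluated at
unit norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import Delaunay, cKDTree

try:  # optional JIT acceleration; pure-numpy fallbacks below are exact
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in supported envs
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


_UNIT_TOL = 1e-6


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    n = np.linalg.norm(v)
    if abs(n - 1.0) > _UNIT_TOL:
        raise ValueError(f"{name} must be unit-norm (|{name}| = {n:.3g})")
    return v


# ---------------------------------------------------------------------------
# Polarity coupling factors
# ---------------------------------------------------------------------------

def polarity_factor_s1(p_i, p_j, r_hat) -> float:
    """AB-AB coupling S1 = (p_i x r_hat).(p_j x r_hat).

    Equals +1 when both AB polarities are parallel and perpendicular to
    the separation (apical sides adjacent) and -1 when they are
    anti-parallel (apical side of one next to the basal side of the
    other).
    """
    p_i = _check_unit(p_i, "p_i")
    p_j = _check_unit(p_j, "p_j")
    r_hat = _check_unit(r_hat, "r_hat")
    return float(np.dot(np.cross(p_i, r_hat), np.cross(p_j, r_hat)))


def polarity_factor_s2(p_i, q_i, p_j, q_j) -> float:
    """AB-PCP orthogonality coupling S2 = (p_i x q_i).(p_j x q_j)."""
    p_i = _check_unit(p_i, "p_i")
    q_i = _check_unit(q_i, "q_i")
    p_j = _check_unit(p_j, "p_j")
    q_j = _check_unit(q_j, "q_j")
    return float(np.dot(np.cross(p_i, q_i), np.cross(p_j, q_j)))


def polarity_factor_s3(q_i, q_j, r_hat) -> float:
    """PCP-PCP coupling S3 = (q_i x r_hat).(q_j x r_hat)."""
    q_i = _check_unit(q_i, "q_i")
    q_j = _check_unit(q_j, "q_j")
    r_hat = _check_unit(r_hat, "r_hat")
    return float(np.dot(np.cross(q_i, r_hat), np.cross(q_j, r_hat)))


def coupling(S1, S2, S3, lambdas_i, lambdas_j, *, angle_gate=False,
             p_dot=None) -> float:
    """Combine the three coupling factors into the attraction scalar S.

    For a pair of cells with per-cell polarity strengths the effective
    strengths are the pairwise means, ``l_k = (l_k,i + l_k,j)/2``, which
    keeps forces equal and opposite and preserves l1+l2+l3 = 1.

    With ``angle_gate`` enabled the S1 (AB) contribution is zeroed when
    the angle between the two AB polarities exceeds pi/2 (``p_dot < 0``),
    the rule used while organoids grow by proliferation.
    """
    li = np.asarray(lambdas_i, dtype=float)
    lj = np.asarray(lambdas_j, dtype=float)
    for lam, name in ((li, "lambdas_i"), (lj, "lambdas_j")):
        if abs(lam.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1, got {lam.sum()!r}")
        if (lam < 0).any():
            raise ValueError(f"{name} must be non-negative")
    l1, l2, l3 = 0.5 * (li + lj)
    if angle_gate:
        if p_dot is None:
            raise ValueError("angle_gate requires p_dot = p_i . p_j")
        if p_dot < 0.0:
            l1 = 0.0
    return float(l1 * S1 + l2 * S2 + l3 * S3)


# ---------------------------------------------------------------------------
# Pair potential
# ---------------------------------------------------------------------------

def pair_potential(r_ij, S, beta=5.0, exponent=1):
    """Evaluate V(r) = exp(-r^m) - S exp(-(r/beta)^m) for m = exponent."""
    r = np.asarray(r_ij, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r_ij must be positive")
    if exponent not in (1, 4):
        raise ValueError("exponent must be 1 or 4")
    out = np.exp(-r ** exponent) - S * np.exp(-((r / beta) ** exponent))
    return float(out) if np.isscalar(r_ij) else out


def equilibrium_distance(S, beta=5.0, exponent=1) -> float:
    """Distance at which the pair potential is stationary (the bound-pair
    rest separation).

    For the exponential potential the stationary point is analytic:
    r* = [beta/(beta-1)] ln(beta/S).  For S = 1, beta = 5 this gives
    r* = 1.25 ln 5 = 2.0118, i.e. two cell radii.  For the quartic
    variant the minimum is located numerically.
    """
    if S <= 0:
        raise ValueError("no finite minimum for S <= 0")
    if exponent == 1:
        return float(beta / (beta - 1.0) * np.log(beta / S))
    res = minimize_scalar(
        lambda r: pair_potential(r, S, beta, exponent),
        bounds=(1e-6, 4.0 * beta), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# Neighborhoods
# ---------------------------------------------------------------------------

@dataclass
class NeighborGraph:
    """Symmetric cell adjacency.

    ``edges`` is an (E, 2) integer array with ``edges[:, 0] < edges[:, 1]``
    and no self-edges.
    """

    n_cells: int
    edges: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if e.size and (e[:, 0] == e[:, 1]).any():
            raise ValueError("self-edges are not allowed")
        e = np.sort(e, axis=1)
        if e.size:
            code = np.unique(e[:, 0] * np.int64(self.n_cells) + e[:, 1])
            e = np.column_stack([code // self.n_cells, code % self.n_cells])
        self.edges = e

    @property
    def degree(self) -> np.ndarray:
        d = np.zeros(self.n_cells, dtype=np.int64)
        if self.edges.size:
            np.add.at(d, self.edges[:, 0], 1)
            np.add.at(d, self.edges[:, 1], 1)
        return d

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    def adjacency_lists(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_cells)]
        for i, j in self.edges:
            adj[int(i)].append(int(j))
            adj[int(j)].append(int(i))
        return adj

    def write_edge_list(self, path) -> None:
        np.savetxt(path, self.edges, fmt="%d", header="i j")

    def exchanges(self, other: "NeighborGraph"):
        """Neighbor-exchange events between two graphs over the same
        cells: returns ``(gained, lost)`` edge sets — the raw material
        of T1 transitions during cell intercalation."""
        if other.n_cells != self.n_cells:
            raise ValueError("graphs cover different cell counts")
        a, b = self.edge_set(), other.edge_set()
        return b - a, a - b


@njit(cache=False)
def _los_keep(pos, idx, dist):  # pragma: no cover - exercised via wrapper
    n, k = idx.shape
    keep = np.zeros((n, k), dtype=np.bool_)
    for i in range(n):
        for a in range(1, k):
            j = idx[i, a]
            rij = dist[i, a]
            half2 = 0.25 * rij * rij
            mx = 0.5 * (pos[i, 0] + pos[j, 0])
            my = 0.5 * (pos[i, 1] + pos[j, 1])
            mz = 0.5 * (pos[i, 2] + pos[j, 2])
            blocked = False
            for b in range(1, k):
                if dist[i, b] > rij + 1e-12:
                    break  # sorted; farther cells cannot block
                if b == a:
                    continue
                c = idx[i, b]
                dx = pos[c, 0] - mx
                dy = pos[c, 1] - my
                dz = pos[c, 2] - mz
                if dx * dx + dy * dy + dz * dz <= half2:
                    blocked = True
                    break
            keep[i, a] = not blocked
    return keep


def find_neighbors(positions, mode="line_of_sight", cutoff=4.0,
                   prefilter_k=100) -> NeighborGraph:
    """Build the interaction graph over cell positions.

    ``line_of_sight``: an edge (i, j) exists iff no third cell lies
    within ``r_ij / 2`` of the pair midpoint (ties block, conservatively).
    Candidate partners are restricted to the ``prefilter_k`` nearest
    cells; any potential blocker of a candidate pair is strictly closer
    than the candidate itself, so the restriction does not change the
    result for pairs inside the prefilter.

    ``voronoi_cutoff``: Delaunay-adjacent pairs closer than ``cutoff``.
    """
    pos = np.ascontiguousarray(positions, dtype=float).reshape(-1, 3)
    n = len(pos)
    if not np.isfinite(pos).all():
        raise ValueError("positions must be finite")
    if n < 2:
        return NeighborGraph(n, np.empty((0, 2), dtype=np.int64))
    tree = cKDTree(pos)
    if mode == "line_of_sight":
        k = min(n, prefilter_k + 1)
        dist, idx = tree.query(pos, k=k)
        if np.min(dist[:, 1]) == 0.0:
            raise ValueError("coincident cell positions")
        keep = _los_keep(pos, idx.astype(np.int64), dist)
        ii, aa = np.nonzero(keep)
        jj = idx[ii, aa]
        lo = np.minimum(ii, jj)
        hi = np.maximum(ii, jj)
        return NeighborGraph(n, np.column_stack([lo, hi]))
    d2, _ = tree.query(pos, k=2)
    if np.min(d2[:, 1]) == 0.0:
        raise ValueError("coincident cell positions")
    if mode == "voronoi_cutoff":
        if n < 5:  # Delaunay needs >= 5 points in 3D; fall back to pairs
            pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
                     if np.linalg.norm(pos[i] - pos[j]) <= cutoff]
            return NeighborGraph(n, np.array(pairs, dtype=np.int64).reshape(-1, 2))
        tri = Delaunay(pos)
        indptr, nbrs = tri.vertex_neighbor_vertices
        pairs = []
        for i in range(n):
            for j in nbrs[indptr[i]:indptr[i + 1]]:
                if j > i and np.linalg.norm(pos[i] - pos[j]) <= cutoff:
                    pairs.append((i, j))
        return NeighborGraph(n, np.array(pairs, dtype=np.int64).reshape(-1, 2))
    raise ValueError(f"unknown neighbor mode {mode!r}")


# ---------------------------------------------------------------------------
# Analytic pair gradients (single-pair reference implementation)
# ---------------------------------------------------------------------------

@dataclass
class PairInteraction:
    """Potential value and gradients for one interacting pair (seen from
    cell i).  Polarity gradients are tangential (projected)."""

    i: int
    j: int
    r_ij: float
    r_hat: np.ndarray
    S: float
    V: float
    dV_dri: np.ndarray
    dV_dpi: np.ndarray
    dV_dqi: np.ndarray


def pair_gradients(position_i, position_j, p_i, p_j, q_i, q_j, lambdas,
                   config, *, in_plane_i=False, i=0, j=1) -> PairInteraction:
    """Potential and analytic gradients for a single pair.

    ``lambdas`` is ``(lambdas_i, lambdas_j)``; effective strengths are the
    pairwise means.  ``config`` supplies ``beta``, ``potential_exponent``
    and ``angle_gate``.  With ``in_plane_i`` the S2 term is dropped from
    the AB-polarity gradient of cell i only (PCP confined to the apical
    plane does not reorient AB polarity).
    """
    ri = np.asarray(position_i, dtype=float)
    rj = np.asarray(position_j, dtype=float)
    dr = rj - ri
    r = float(np.linalg.norm(dr))
    if r == 0.0:
        raise ValueError("coincident cells")
    r_hat = dr / r
    p_i = _check_unit(p_i, "p_i")
    p_j = _check_unit(p_j, "p_j")
    q_i = _check_unit(q_i, "q_i")
    q_j = _check_unit(q_j, "q_j")
    li = np.asarray(lambdas[0], dtype=float)
    lj = np.asarray(lambdas[1], dtype=float)
    l1, l2, l3 = 0.5 * (li + lj)
    beta = config.beta
    m = config.potential_exponent

    ai, aj, pp = p_i @ r_hat, p_j @ r_hat, p_i @ p_j
    bi, bj, qq = q_i @ r_hat, q_j @ r_hat, q_i @ q_j
    piqj, qipj = p_i @ q_j, q_i @ p_j
    S1 = pp - ai * aj
    S2 = pp * qq - piqj * qipj
    S3 = qq - bi * bj
    l1g = 0.0 if (getattr(config, "angle_gate", False) and pp < 0.0) else l1
    S = l1g * S1 + l2 * S2 + l3 * S3

    u = np.exp(-(r ** m))
    w = np.exp(-((r / beta) ** m))
    V = u - S * w
    dVdr = -m * r ** (m - 1) * u + S * (m * r ** (m - 1) / beta ** m) * w

    dS1_dri = (aj * p_i + ai * p_j - 2.0 * ai * aj * r_hat) / r
    dS3_dri = (bj * q_i + bi * q_j - 2.0 * bi * bj * r_hat) / r
    dV_dri = -dVdr * r_hat - w * (l1g * dS1_dri + l3 * dS3_dri)

    dS1_dpi = p_j - aj * r_hat - S1 * p_i
    dS2_dpi = qq * p_j - qipj * q_j - S2 * p_i
    l2_i = 0.0 if in_plane_i else l2
    dV_dpi = -w * (l1g * dS1_dpi + l2_i * dS2_dpi)

    dS2_dqi = pp * q_j - piqj * p_j - S2 * q_i
    dS3_dqi = q_j - bj * r_hat - S3 * q_i
    dV_dqi = -w * (l2 * dS2_dqi + l3 * dS3_dqi)

    return PairInteraction(i=i, j=j, r_ij=r, r_hat=r_hat, S=float(S),
                           V=float(V), dV_dri=dV_dri, dV_dpi=dV_dpi,
                           dV_dqi=dV_dqi)


# ---------------------------------------------------------------------------
# Vectorized system gradients (per-step kernel)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _system_gradients_kernel(pos, p, q, lam, edges, beta, m, angle_gate,
                             in_plane):  # pragma: no cover - via wrapper
    n = pos.shape[0]
    ne = edges.shape[0]
    grad_r = np.zeros((n, 3))
    grad_p = np.zeros((n, 3))
    grad_q = np.zeros((n, 3))
    energy = np.zeros(n)
    for e in range(ne):
        i = edges[e, 0]
        j = edges[e, 1]
        dr = pos[j] - pos[i]
        r = np.sqrt(dr[0] ** 2 + dr[1] ** 2 + dr[2] ** 2)
        rh = dr / r
        l1 = 0.5 * (lam[i, 0] + lam[j, 0])
        l2 = 0.5 * (lam[i, 1] + lam[j, 1])
        l3 = 0.5 * (lam[i, 2] + lam[j, 2])
        pi = p[i]
        pj = p[j]
        qi = q[i]
        qj = q[j]
        ai = pi @ rh
        aj = pj @ rh
        pp = pi @ pj
        bi = qi @ rh
        bj = qj @ rh
        qq = qi @ qj
        piqj = pi @ qj
        qipj = qi @ pj
        S1 = pp - ai * aj
        S2 = pp * qq - piqj * qipj
        S3 = qq - bi * bj
        l1g = l1
        if angle_gate and pp < 0.0:
            l1g = 0.0
        S = l1g * S1 + l2 * S2 + l3 * S3
        if m == 1:
            u = np.exp(-r)
            w = np.exp(-r / beta)
            dVdr = -u + S * w / beta
        else:
            u = np.exp(-(r ** 4))
            w = np.exp(-((r / beta) ** 4))
            rp = 4.0 * r ** 3
            dVdr = -rp * u + S * (rp / beta ** 4) * w
        V = u - S * w
        energy[i] += V
        energy[j] += V

        dS1_dri = (aj * pi + ai * pj - 2.0 * ai * aj * rh) / r
        dS3_dri = (bj * qi + bi * qj - 2.0 * bi * bj * rh) / r
        g = -dVdr * rh - w * (l1g * dS1_dri + l3 * dS3_dri)
        grad_r[i] += g
        grad_r[j] -= g

        # AB polarity gradients (tangential); S2 dropped for in-plane cells
        l2i = 0.0 if in_plane[i] else l2
        l2j = 0.0 if in_plane[j] else l2
        dS1_dpi = pj - aj * rh - S1 * pi
        dS2_dpi = qq * pj - qipj * qj - S2 * pi
        grad_p[i] += -w * (l1g * dS1_dpi + l2i * dS2_dpi)
        dS1_dpj = pi - ai * rh - S1 * pj
        dS2_dpj = qq * pi - piqj * qi - S2 * pj
        grad_p[j] += -w * (l1g * dS1_dpj + l2j * dS2_dpj)

        dS2_dqi = pp * qj - piqj * pj - S2 * qi
        dS3_dqi = qj - bj * rh - S3 * qi
        grad_q[i] += -w * (l2 * dS2_dqi + l3 * dS3_dqi)
        dS2_dqj = pp * qi - qipj * pi - S2 * qj
        dS3_dqj = qi - bi * rh - S3 * qj
        grad_q[j] += -w * (l2 * dS2_dqj + l3 * dS3_dqj)
    return grad_r, grad_p, grad_q, energy


def system_gradients(positions, ab, pcp, lambdas, graph: NeighborGraph,
                     config, pcp_in_plane=None):
    """Sum analytic pair gradients and energies over all graph edges.

    Returns ``(grad_r, grad_p, grad_q, energy_per_cell)`` where each
    gradient array is (N, 3) and ``energy_per_cell[i]`` is the sum of
    pair potentials over i's neighbors.
    """
    n = len(positions)
    if pcp_in_plane is None:
        pcp_in_plane = np.zeros(n, dtype=bool)
    edges = np.ascontiguousarray(graph.edges, dtype=np.int64)
    if edges.size == 0:
        z = np.zeros((n, 3))
        return z, z.copy(), z.copy(), np.zeros(n)
    return _system_gradients_kernel(
        np.ascontiguousarray(positions, dtype=float),
        np.ascontiguousarray(ab, dtype=float),
        np.ascontiguousarray(pcp, dtype=float),
        np.ascontiguousarray(lambdas, dtype=float),
        edges, float(config.beta), int(config.potential_exponent),
        bool(config.angle_gate),
        np.ascontiguousarray(pcp_in_plane, dtype=np.bool_),
    )
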
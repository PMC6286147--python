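"""Simulation state, configuration, and initial-condition generators.

A system is a set of N point-particle cells, each carrying a position
(in cell-radius units), an apical-basal (AB) polarity unit vector ``p``,
a planar-cell-polarity (PCP) unit vector ``q``, and a triple of polarity
strengths ``(l1, l2, l3)`` with ``l1 + l2 + l3 = 1``.  Generators build
the standard starting configurations: a compact bulk aggregate with
random AB polarity, and a hollow sphere with radially outward AB
polarity and, optionally, PCP whirling azimuthally around an axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

STATE_COLUMNS = ["x", "y", "z", "px", "py", "pz", "qx", "qy", "qz",
                 "l1", "l2", "l3", "fixed", "pcp_active"]


@dataclass
class ModelConfig:
    """Model and integrator parameters.

    beta : ratio of attraction range to repulsion range (> 1).
    dt : Euler time step (time units are arbitrary but consistent).
    eta : amplitude of the uncorrelated Gaussian noise added to every
        Cartesian component of the position and polarity rates.
    potential_exponent : 1 for the exponential potential, 4 for the
        quartic-exponent variant.
    neighbor_mode : ``line_of_sight`` (midpoint rule) or
        ``voronoi_cutoff`` (Delaunay adjacency within ``cutoff``).
    prefilter_k : number of nearest candidate neighbors examined by the
        line-of-sight rule.
    angle_gate : zero the AB attraction for pairs whose AB polarities
        differ by more than pi/2 (used in proliferating organoids).
    graph_stride : rebuild the neighbor graph every this many steps.
    """

    beta: float = 5.0
    dt: float = 0.1
    eta: float = 1e-4
    potential_exponent: int = 1
    neighbor_mode: str = "line_of_sight"
    cutoff: float = 4.0
    prefilter_k: int = 100
    seed: int | None = None
    angle_gate: bool = False
    pressure_P: float = 0.0
    force_k: float = 0.0
    force_sigma: float = 10.0
    generation_time: float = float("inf")
    graph_stride: int = 1

    def __post_init__(self):
        if self.beta <= 1:
            raise ValueError("beta must exceed 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.potential_exponent not in (1, 4):
            raise ValueError("potential_exponent must be 1 or 4")
        if self.neighbor_mode not in ("line_of_sight", "voronoi_cutoff"):
            raise ValueError(f"unknown neighbor_mode {self.neighbor_mode!r}")
        if self.pressure_P < 0:
            raise ValueError("pressure_P must be non-negative")
        if self.force_sigma <= 0:
            raise ValueError("force_sigma must be positive")
        if self.graph_stride < 1:
            raise ValueError("graph_stride must be >= 1")


@dataclass
class CellState:
    """Arrays describing all cells at one instant.

    ``positions`` (N, 3); ``ab_polarity`` and ``pcp`` (N, 3) unit rows;
    ``lambdas`` (N, 3) non-negative rows summing to 1;
    ``fixed_polarity_mask`` marks cells whose polarities never rotate;
    ``pcp_in_plane_mask`` marks cells whose PCP is confined to the
    apical plane (PCP then cannot reorient AB polarity);
    ``pcp_active_mask`` marks cells whose PCP is meaningful.
    """

    positions: np.ndarray
    ab_polarity: np.ndarray
    pcp: np.ndarray
    lambdas: np.ndarray
    fixed_polarity_mask: np.ndarray
    pcp_in_plane_mask: np.ndarray
    pcp_active_mask: np.ndarray
    time: float = 0.0

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    def copy(self) -> "CellState":
        return CellState(
            positions=self.positions.copy(),
            ab_polarity=self.ab_polarity.copy(),
            pcp=self.pcp.copy(),
            lambdas=self.lambdas.copy(),
            fixed_polarity_mask=self.fixed_polarity_mask.copy(),
            pcp_in_plane_mask=self.pcp_in_plane_mask.copy(),
            pcp_active_mask=self.pcp_active_mask.copy(),
            time=self.time,
        )

    def validate(self) -> None:
        n = self.n_cells
        if n < 1:
            raise ValueError("state must contain at least one cell")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions must be finite")
        for arr, name in ((self.ab_polarity, "ab_polarity"),
                          (self.pcp, "pcp")):
            norms = np.linalg.norm(arr, axis=1)
            if name == "pcp":
                norms = norms[self.pcp_active_mask] if self.pcp_active_mask.any() else norms[:0]
            if norms.size and np.max(np.abs(norms - 1.0)) > 1e-9:
                raise ValueError(f"{name} rows must be unit vectors")
        sums = self.lambdas.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) > 1e-12:
            raise ValueError("lambda triples must sum to 1")
        if (self.lambdas < 0).any():
            raise ValueError("lambda values must be non-negative")

    # -- tabular round trip ------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "x": self.positions[:, 0], "y": self.positions[:, 1],
            "z": self.positions[:, 2],
            "px": self.ab_polarity[:, 0], "py": self.ab_polarity[:, 1],
            "pz": self.ab_polarity[:, 2],
            "qx": self.pcp[:, 0], "qy": self.pcp[:, 1],
            "qz": self.pcp[:, 2],
            "l1": self.lambdas[:, 0], "l2": self.lambdas[:, 1],
            "l3": self.lambdas[:, 2],
            "fixed": self.fixed_polarity_mask.astype(int),
            "pcp_active": self.pcp_active_mask.astype(int),
        })
        df["pcp_in_plane"] = self.pcp_in_plane_mask.astype(int)
        return df

    def write_csv(self, path) -> None:
        """Write one row per cell.  The canonical columns are
        STATE_COLUMNS; ``pcp_in_plane`` is appended so the round trip is
        lossless."""
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time: float = 0.0) -> "CellState":
        in_plane = (df["pcp_in_plane"].to_numpy(dtype=bool)
                    if "pcp_in_plane" in df.columns
                    else np.zeros(len(df), dtype=bool))
        return cls(
            positions=df[["x", "y", "z"]].to_numpy(dtype=float),
            ab_polarity=df[["px", "py", "pz"]].to_numpy(dtype=float),
            pcp=df[["qx", "qy", "qz"]].to_numpy(dtype=float),
            lambdas=df[["l1", "l2", "l3"]].to_numpy(dtype=float),
            fixed_polarity_mask=df["fixed"].to_numpy(dtype=bool),
            pcp_in_plane_mask=in_plane,
            pcp_active_mask=df["pcp_active"].to_numpy(dtype=bool),
            time=time,
        )

    @classmethod
    def read_csv(cls, path, time: float = 0.0) -> "CellState":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls.from_dataframe(df, time=time)


def _random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _default_state(positions, ab, pcp, time=0.0) -> CellState:
    n = len(positions)
    lam = np.zeros((n, 3))
    lam[:, 0] = 1.0
    return CellState(
        positions=np.asarray(positions, dtype=float),
        ab_polarity=np.asarray(ab, dtype=float),
        pcp=np.asarray(pcp, dtype=float),
        lambdas=lam,
        fixed_polarity_mask=np.zeros(n, dtype=bool),
        pcp_in_plane_mask=np.zeros(n, dtype=bool),
        pcp_active_mask=np.zeros(n, dtype=bool),
        time=time,
    )


def _rsa_ball(n: int, radius: float, min_sep: float,
              rng: np.random.Generator) -> np.ndarray:
    """Random sequential placement of n points in a ball, rejecting pairs
    closer than min_sep, using a uniform grid hash."""
    cell = min_sep
    grid: dict[tuple[int, int, int], list[int]] = {}
    pts = np.empty((n, 3))
    count = 0
    attempts = 0
    max_attempts = 2000 * n + 10000
    min2 = min_sep * min_sep
    while count < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "aggregate packing failed; lower the density "
                "(increase radius_scale)")
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        r = radius * rng.random() ** (1.0 / 3.0)
        x = r * u
        key = tuple(np.floor(x / cell).astype(int))
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for idx in grid.get((key[0] + dx, key[1] + dy,
                                         key[2] + dz), ()):
                        d = x - pts[idx]
                        if d @ d < min2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[count] = x
            grid.setdefault(key, []).append(count)
            count += 1
    return pts


def _relax_nonpolar(positions: np.ndarray, config: ModelConfig,
                    n_steps: int = 50) -> np.ndarray:
    """Noiseless gradient-descent steps with S = 1 (non-polar attraction)
    to remove packing artifacts from the initial aggregate."""
    from .interactions import find_neighbors

    pos = positions.copy()
    n = len(pos)
    dummy = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))
    lam = np.zeros((n, 3))
    lam[:, 0] = 1.0
    for _ in range(n_steps):
        graph = find_neighbors(pos, mode=config.neighbor_mode,
                               cutoff=config.cutoff,
                               prefilter_k=config.prefilter_k)
        if graph.edges.size == 0:
            break
        e = graph.edges
        dr = pos[e[:, 1]] - pos[e[:, 0]]
        r = np.linalg.norm(dr, axis=1)
        rh = dr / r[:, None]
        m = config.potential_exponent
        dVdr = (-m * r ** (m - 1) * np.exp(-r ** m)
                + (m * r ** (m - 1) / config.beta ** m)
                * np.exp(-((r / config.beta) ** m)))
        f = dVdr[:, None] * rh  # force on cell i along +rh when dVdr > 0
        force = np.zeros_like(pos)
        np.add.at(force, e[:, 0], f)
        np.add.at(force, e[:, 1], -f)
        pos += config.dt * force
    return pos


def make_bulk_aggregate(n: int, radius_scale: float = 1.0,
                        rng: np.random.Generator | None = None,
                        config: ModelConfig | None = None,
                        relax_steps: int = 50) -> CellState:
    """Compact ball of n cells with random AB polarity directions.

    Cells are placed by random sequential insertion (minimum separation
    1.6 cell radii) in a ball sized so the relaxed nearest-neighbor
    spacing is about two cell radii, then relaxed for ``relax_steps``
    noiseless steps with S = 1.  PCP is inactive; lambdas = (1, 0, 0).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    config = ModelConfig() if config is None else config
    if n == 1:
        pos = np.zeros((1, 3))
    else:
        number_density = 0.15  # cells per unit volume ~ spacing 2.2
        radius = radius_scale * (3.0 * n / (4.0 * np.pi * number_density)) ** (1 / 3)
        pos = _rsa_ball(n, radius, 1.6, rng)
        if relax_steps:
            pos = _relax_nonpolar(pos, config, relax_steps)
    ab = _random_unit_vectors(n, rng)
    pcp = _random_unit_vectors(n, rng)
    return _default_state(pos, ab, pcp)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (spiral points)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def make_hollow_sphere(n: int, radius: float | None = None,
                       pcp_whirl: bool = False,
                       whirl_axis=(0.0, 0.0, 1.0),
                       rng: np.random.Generator | None = None) -> CellState:
    """Cells on a hollow sphere with AB polarity radially outward.

    Positions are a Fibonacci spiral lattice; the default radius gives a
    surface density of one cell per hexagonal-packing area at spacing 2
    cell radii.  With ``pcp_whirl`` PCP is set azimuthal about
    ``whirl_axis`` (q = axis x r_hat, normalized), orthogonal to the
    radial AB polarity.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    rng = np.random.default_rng() if rng is None else rng
    if radius is None:
        radius = float(np.sqrt(n * 2.0 * np.sqrt(3.0) / (4.0 * np.pi)))
    rhat = fibonacci_sphere(n)
    pos = radius * rhat
    ab = rhat.copy()
    axis = np.asarray(whirl_axis, dtype=float)
    axis /= np.linalg.norm(axis)
    q = np.cross(axis, rhat)
    norms = np.linalg.norm(q, axis=1)
    bad = norms < 1e-12
    if bad.any():  # cell exactly at a pole: any tangent direction works
        fallback = np.cross(rhat[bad], np.array([1.0, 0.0, 0.0]))
        q[bad] = fallback
        norms = np.linalg.norm(q, axis=1)
    q /= norms[:, None]
    state = _default_state(pos, ab, q)
    state.pcp_active_mask[:] = pcp_whirl
    return state


_FIELDS = ("radial_point", "radial_axis", "planar")


def apply_polarity_field(state: CellState, field: str, fix: bool = True,
                         center=None, axis=(0.0, 0.0, 1.0),
                         plane_normal=(0.0, 0.0, 1.0),
                         plane_offset: float = 0.0) -> CellState:
    """Overwrite AB polarities with a symmetric boundary-condition field.

    ``radial_point``: radially out from ``center`` (default the center
    of mass); ``radial_axis``: radially out from the line through the
    origin along ``axis``; ``planar``: away from the plane with normal
    ``plane_normal`` through ``plane_offset``.  Cells exactly on the
    symmetry locus get +x (radial fields) or +normal (planar) with a
    warning.  With ``fix`` the polarities are frozen for all time.
    """
    if field not in _FIELDS:
        raise ValueError(f"field must be one of {_FIELDS}")
    out = state.copy()
    pos = out.positions
    if field == "radial_point":
        c = pos.mean(axis=0) if center is None else np.asarray(center, float)
        v = pos - c
    elif field == "radial_axis":
        a = np.asarray(axis, dtype=float)
        a /= np.linalg.norm(a)
        v = pos - np.outer(pos @ a, a)
    else:
        nrm = np.asarray(plane_normal, dtype=float)
        nrm /= np.linalg.norm(nrm)
        signed = pos @ nrm - plane_offset
        v = np.sign(signed)[:, None] * nrm
        v[signed == 0.0] = 0.0
    norms = np.linalg.norm(v, axis=1)
    degenerate = norms < 1e-12
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} cell(s) on the {field} symmetry locus; "
            "assigned the documented tie-break direction")
        tiebreak = (np.array([0.0, 0.0, 1.0]) if field == "planar"
                    else np.array([1.0, 0.0, 0.0]))
        v[degenerate] = tiebreak
        norms[degenerate] = 1.0
    out.ab_polarity = v / norms[:, None]
    if fix:
        out.fixed_polarity_mask[:] = True
    return out
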
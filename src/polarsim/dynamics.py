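"""Time integration of the overdamped polarity-coupled dynamics.

Positions and both polarity vectors evolve by gradient descent on the
summed pair potential plus uncorrelated Gaussian noise,

    dr_i/dt = -dV_i/dr_i + eta * xi,
    dp_i/dt = -dV_i/dp_i + eta * xi,
    dq_i/dt = -dV_i/dq_i + eta * xi,

integrated with the explicit Euler method; polarity vectors are
renormalized after every step.  Polarity differentiation is performed in
Cartesian coordinates (tangential gradients), so renormalization keeps
the vectors on the unit sphere.  The noise term is a per-step Gaussian
kick of amplitude ``eta`` added to the rate (so the per-step displacement
is ``dt * eta * xi``); ``eta`` is therefore tied to the chosen ``dt``.

Two external fields are available: an inward "medium resistance"
pressure whose magnitude grows linearly from the center of mass to the
outermost cell (constant in time at the periphery of a growing sphere),
and a gastrulation force acting on AB polarity that tilts polarities
away from the anterior-posterior (z) axis with a Gaussian profile in the
distance from that axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .interactions import NeighborGraph, find_neighbors, system_gradients
from .state import CellState, ModelConfig


@dataclass
class ExternalFields:
    """External force terms.

    pressure_P : stiffness of the surrounding medium (inward surface
        force of magnitude P * r / r_max); 0 disables.
    force_k, force_sigma : strength and Gaussian width of the
        gastrulation force on AB polarity; k = 0 disables.  The force is
        applied as a per-step reorientation increment (not multiplied by
        dt), so like the noise amplitude its strength is tied to dt.
    force_mask : boolean per-cell mask the AB force acts on (None = all).
    pcp_pin_mask : cells whose PCP is held as a whirl boundary condition
        about ``pcp_pin_axis`` (re-imposed after every step, projected
        into the apical plane); None disables.
    """

    pressure_P: float = 0.0
    force_k: float = 0.0
    force_sigma: float = 10.0
    force_mask: np.ndarray | None = None
    pcp_pin_mask: np.ndarray | None = None
    pcp_pin_axis: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.pressure_P < 0:
            raise ValueError("pressure_P must be non-negative")
        if self.force_sigma <= 0:
            raise ValueError("force_sigma must be positive")


def pressure_force(positions, P, center_of_mass=None) -> np.ndarray:
    """Inward medium-resistance force, magnitude P * r / r_max.

    ``r`` is the distance from the center of mass and ``r_max`` the
    distance of the outermost cell, so peripheral cells always feel a
    force of magnitude P while cells deep inside folds feel less.
    """
    pos = np.asarray(positions, dtype=float)
    if P < 0:
        raise ValueError("P must be non-negative")
    com = pos.mean(axis=0) if center_of_mass is None else np.asarray(
        center_of_mass, dtype=float)
    v = pos - com
    r = np.linalg.norm(v, axis=1)
    rmax = r.max() if len(r) else 0.0
    if P == 0.0 or rmax == 0.0:
        return np.zeros_like(pos)
    return -(P / rmax) * v


def gastrulation_ab_force(positions, k, sigma, mask=None) -> np.ndarray:
    """External reorientation field on AB polarity driving invagination.

    For each selected cell at in-plane radius rho = sqrt(x^2 + y^2) the
    AB polarity receives ``-k * rho_hat * exp(-rho^2 / sigma^2)`` per
    step, where ``rho_hat`` points from the z-axis to the cell.  Tilting
    AB polarity toward the axis (strongest for cells near it) makes the
    epithelial normals converge and bends the sheet inward; cells
    exactly on the axis receive no force (the direction is undefined
    there).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pos = np.asarray(positions, dtype=float)
    out = np.zeros_like(pos)
    if k == 0.0:
        return out
    rho_vec = pos.copy()
    rho_vec[:, 2] = 0.0
    rho = np.linalg.norm(rho_vec, axis=1)
    ok = rho > 1e-12
    if mask is not None:
        ok &= np.asarray(mask, dtype=bool)
    amp = -k * np.exp(-(rho[ok] ** 2) / sigma ** 2)
    out[ok] = amp[:, None] * (rho_vec[ok] / rho[ok, None])
    return out


def _renormalize(vectors: np.ndarray, rows: np.ndarray, what: str) -> None:
    norms = np.linalg.norm(vectors[rows], axis=1)
    if norms.size and norms.min() < 1e-12:
        bad = int(np.flatnonzero(norms < 1e-12)[0])
        raise FloatingPointError(
            f"{what} collapsed to zero norm during update (cell row {bad}); "
            "reduce dt or eta")
    vectors[rows] /= norms[:, None]


def step(state: CellState, graph: NeighborGraph, config: ModelConfig,
         fields: ExternalFields | None = None,
         rng: np.random.Generator | None = None) -> CellState:
    """Advance the state by one Euler step (in place) and return it.

    Cells with ``fixed_polarity_mask`` skip both polarity updates.
    Cells with ``pcp_in_plane_mask`` use l2 = 0 in the AB update and have
    PCP re-projected onto the plane orthogonal to AB polarity after the
    update.  Noise vectors are drawn in the order positions, AB, PCP so
    trajectories are bitwise reproducible for a fixed generator state.
    """
    if config.dt <= 0:
        raise ValueError("dt must be positive")
    fields = ExternalFields() if fields is None else fields
    rng = np.random.default_rng() if rng is None else rng
    n = state.n_cells
    dt = config.dt
    grad_r, grad_p, grad_q, _ = system_gradients(
        state.positions, state.ab_polarity, state.pcp, state.lambdas,
        graph, config, pcp_in_plane=state.pcp_in_plane_mask)

    vel = -grad_r
    if fields.pressure_P > 0.0:
        vel += pressure_force(state.positions, fields.pressure_P)
    dp = -grad_p
    dq = -grad_q
    if config.eta > 0.0:
        vel += config.eta * rng.standard_normal((n, 3))
        dp += config.eta * rng.standard_normal((n, 3))
        dq += config.eta * rng.standard_normal((n, 3))

    state.positions += dt * vel
    free = ~state.fixed_polarity_mask
    rows = np.flatnonzero(free)
    if rows.size:
        state.ab_polarity[rows] += dt * dp[rows]
        if fields.force_k != 0.0:
            # per-step reorientation kick on AB polarity
            kick = gastrulation_ab_force(state.positions, fields.force_k,
                                         fields.force_sigma,
                                         fields.force_mask)
            state.ab_polarity[rows] += kick[rows]
        _renormalize(state.ab_polarity, rows, "AB polarity")
        state.pcp[rows] += dt * dq[rows]
        _renormalize(state.pcp, rows, "PCP")
        if fields.pcp_pin_mask is not None:
            pin = np.flatnonzero(free & fields.pcp_pin_mask)
            if pin.size:
                axis = np.asarray(fields.pcp_pin_axis, dtype=float)
                axis /= np.linalg.norm(axis)
                az = np.cross(axis, state.positions[pin])
                p = state.ab_polarity[pin]
                az -= np.sum(az * p, axis=1, keepdims=True) * p
                norms = np.linalg.norm(az, axis=1)
                ok = norms > 1e-9
                state.pcp[pin[ok]] = az[ok] / norms[ok, None]
        plane = np.flatnonzero(free & state.pcp_in_plane_mask)
        if plane.size:
            q = state.pcp[plane]
            p = state.ab_polarity[plane]
            q -= (np.sum(q * p, axis=1, keepdims=True)) * p
            state.pcp[plane] = q
            _renormalize(state.pcp, plane, "in-plane PCP")
    state.time += dt
    return state


@dataclass
class Trajectory:
    """Sampled frames and per-frame metrics of a simulation run."""

    frames: list = dataclass_field(default_factory=list)
    frame_times: list = dataclass_field(default_factory=list)
    records: list = dataclass_field(default_factory=list)

    @property
    def metrics(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def run(state: CellState, config: ModelConfig, n_steps: int,
        fields: ExternalFields | None = None,
        rng: np.random.Generator | None = None,
        frame_stride: int | None = None,
        metrics_stride: int | None = None,
        metrics_fn=None) -> tuple[CellState, Trajectory]:
    """Integrate ``n_steps`` Euler steps, rebuilding the neighbor graph
    every ``config.graph_stride`` steps.

    ``metrics_fn(state, graph, config) -> dict`` is sampled every
    ``metrics_stride`` steps; by default it records mean/spread of the
    energy per cell and of the neighbor count.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    traj = Trajectory()
    graph = None
    for k in range(n_steps):
        if graph is None or k % config.graph_stride == 0:
            graph = find_neighbors(state.positions, mode=config.neighbor_mode,
                                   cutoff=config.cutoff,
                                   prefilter_k=config.prefilter_k)
        if metrics_stride and k % metrics_stride == 0:
            traj.records.append(_sample_metrics(state, graph, config,
                                                metrics_fn))
        if frame_stride and k % frame_stride == 0:
            traj.frames.append(state.copy())
            traj.frame_times.append(state.time)
        step(state, graph, config, fields, rng)
    graph = find_neighbors(state.positions, mode=config.neighbor_mode,
                           cutoff=config.cutoff,
                           prefilter_k=config.prefilter_k)
    if metrics_stride:
        traj.records.append(_sample_metrics(state, graph, config, metrics_fn))
    if frame_stride:
        traj.frames.append(state.copy())
        traj.frame_times.append(state.time)
    return state, traj


def _sample_metrics(state, graph, config, metrics_fn) -> dict:
    from .metrics import energy_per_cell

    rec = {"time": state.time, "n_cells": state.n_cells}
    e = energy_per_cell(state, graph, config)
    deg = graph.degree
    rec.update(energy_mean=float(e.mean()), energy_std=float(e.std()),
               neighbors_mean=float(deg.mean()),
               neighbors_std=float(deg.std()))
    if metrics_fn is not None:
        rec.update(metrics_fn(state, graph, config))
    return rec
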
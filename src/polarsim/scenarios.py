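"""Preset experiments: bulk aggregates, boundary conditions, growing
organoids, PCP-driven tubes, and sea-urchin-style gastrulation.

Each builder wires the state generators, the integrator, proliferation,
and the metrics into one reproducible run.  Default sizes are reduced
from the thousands-of-cells originals so a full sweep runs at desk
scale; every result carries a manifest (parameters + seed) sufficient
to reproduce it bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from . import metrics as _metrics
from .dynamics import ExternalFields, Trajectory, run
from .interactions import find_neighbors
from .proliferation import GrowthSchedule, growth_driver
from .state import (CellState, ModelConfig, apply_polarity_field,
                    make_bulk_aggregate, make_hollow_sphere)

BOUNDARY_FIELDS = ("radial_point", "radial_axis", "planar",
                   "dynamic_high_noise")


@dataclass
class ScenarioResult:
    """Outcome of one preset run: final state, sampled trajectory, the
    reproduction manifest, and scenario-specific measurements."""

    name: str
    manifest: dict
    state: CellState
    trajectory: Trajectory
    extras: dict = dataclass_field(default_factory=dict)


def _graph(state: CellState, config: ModelConfig):
    return find_neighbors(state.positions, mode=config.neighbor_mode,
                          cutoff=config.cutoff,
                          prefilter_k=config.prefilter_k)


def scenario_bulk_random(n: int = 300, eta: float = 1e-4,
                         t_end: float = 500.0, dt: float = 0.2,
                         seed: int = 0, frame_stride: int | None = None,
                         metrics_stride: int | None = 50) -> ScenarioResult:
    """Compact aggregate with random AB polarity directions.

    The aggregate expands rapidly, then settles into a stable complex
    morphology of interconnected channels whose mean energy per cell
    plateaus above the hollow-sphere value for the same cell count.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    rng = np.random.default_rng(seed)
    config = ModelConfig(dt=dt, eta=eta, seed=seed)
    state = make_bulk_aggregate(n, rng=rng, config=config)
    n_steps = int(round(t_end / dt))
    state, traj = run(state, config, n_steps, rng=rng,
                      frame_stride=frame_stride,
                      metrics_stride=metrics_stride)
    manifest = dict(scenario="bulk_random", n=n, eta=eta, t_end=t_end,
                    dt=dt, seed=seed)
    return ScenarioResult("bulk_random", manifest, state, traj,
                          extras={"config": config})


def hollow_sphere_reference_energy(n: int, config: ModelConfig | None = None,
                                   t_relax: float = 50.0,
                                   seed: int = 0) -> float:
    """Mean energy per cell of a radially polarized hollow sphere with n
    cells, relaxed noiselessly with polarities held radial throughout
    (the reference configuration for bulk-aggregate comparisons)."""
    config = ModelConfig(dt=0.2, eta=0.0) if config is None else config
    rng = np.random.default_rng(seed)
    state = make_hollow_sphere(n, rng=rng)
    state = apply_polarity_field(state, "radial_point", fix=True,
                                 center=np.zeros(3))
    state, _ = run(state, config, int(round(t_relax / config.dt)), rng=rng)
    graph = _graph(state, config)
    return float(_metrics.energy_per_cell(state, graph, config).mean())


def scenario_boundary(field: str, n: int = 600, t_end: float = 300.0,
                      dt: float = 0.2, eta: float = 0.1, seed: int = 0,
                      frame_stride: int | None = None,
                      metrics_stride: int | None = None) -> ScenarioResult:
    """Boundary-condition experiments on an initially compact aggregate.

    Fixed polarity fields produce a single hollow sphere
    (``radial_point``), a hollow tube (``radial_axis``), or two parallel
    sheets (``planar``).  ``dynamic_high_noise`` starts from the same
    symmetric (radial) polarity configuration but lets polarities evolve
    freely under strong noise (eta = 1), which yields nested
    "Russian-doll" hollow spheres.
    """
    if field not in BOUNDARY_FIELDS:
        raise ValueError(f"field must be one of {BOUNDARY_FIELDS}")
    rng = np.random.default_rng(seed)
    high_noise = field == "dynamic_high_noise"
    config = ModelConfig(dt=dt, eta=(1.0 if high_noise else eta), seed=seed)
    state = make_bulk_aggregate(n, rng=rng, config=config)
    if high_noise:
        state = apply_polarity_field(state, "radial_point", fix=False,
                                     center=np.zeros(3))
    else:
        state = apply_polarity_field(state, field, fix=True,
                                     center=np.zeros(3))
    n_steps = int(round(t_end / dt))
    state, traj = run(state, config, n_steps, rng=rng,
                      frame_stride=frame_stride,
                      metrics_stride=metrics_stride)
    graph = _graph(state, config)
    extras: dict = {"config": config, "graph": graph}
    com = state.positions.mean(axis=0)
    rel = state.positions - com
    if field == "radial_point":
        r = np.linalg.norm(rel, axis=1)
        extras["radius_cv"] = float(r.std() / r.mean())
    elif field == "radial_axis":
        rho = np.linalg.norm(rel[:, :2], axis=1)
        central = np.abs(rel[:, 2]) <= 0.5 * np.quantile(np.abs(rel[:, 2]), 0.95)
        rho_c = rho[central]
        extras["axial_distance_cv"] = float(rho_c.std() / rho_c.mean())
    elif field == "planar":
        up = state.ab_polarity[:, 2] > 0
        extras["sheet_separation"] = float(
            rel[up, 2].mean() - rel[~up, 2].mean())
        extras["sheet_thickness"] = (float(rel[up, 2].std()),
                                     float(rel[~up, 2].std()))
    else:
        extras["n_shells"] = _metrics.count_shells(state, graph)
    manifest = dict(scenario="boundary", field=field, n=n, t_end=t_end,
                    dt=dt, eta=config.eta, seed=seed)
    return ScenarioResult("boundary", manifest, state, traj, extras)


def scenario_organoid(mode: str = "growth", t_G: float = 200.0,
                      P: float = 0.0, n_max: int = 1000, n0: int = 200,
                      dt: float = 0.2, eta: float = 1e-4, seed: int = 0,
                      t_relax: float = 0.0,
                      metrics_stride: int | None = None) -> ScenarioResult:
    """Growing organoid, folding either by rapid proliferation or by
    pressure from the surrounding medium.

    ``growth`` mode grows with generation time ``t_G`` and no pressure;
    ``pressure`` mode additionally applies the inward medium-resistance
    force of stiffness ``P``.  The AB attraction is gated off for pairs
    with polarity misaligned by more than pi/2 while growing.  After the
    population reaches ``n_max`` the system relaxes for ``t_relax`` time
    units, and the local-minima (fold) count is measured.
    """
    if mode not in ("growth", "pressure"):
        raise ValueError("mode must be 'growth' or 'pressure'")
    if mode == "growth":
        P = 0.0
    rng = np.random.default_rng(seed)
    config = ModelConfig(dt=dt, eta=eta, seed=seed, angle_gate=True,
                         generation_time=t_G)
    fields = ExternalFields(pressure_P=P)
    state = make_hollow_sphere(n0, rng=rng)
    state = apply_polarity_field(state, "radial_point", fix=False,
                                 center=np.zeros(3))
    schedule = GrowthSchedule(n0=n0, generation_time=t_G, n_max=n_max)
    state, traj, events = growth_driver(state, schedule, config, fields,
                                        rng=rng,
                                        metrics_stride=metrics_stride)
    if t_relax > 0:
        state, _ = run(state, config, int(round(t_relax / dt)), fields,
                       rng=rng)
    graph = _graph(state, config)
    n_min = _metrics.count_local_minima(state, graph)
    extras = {"config": config, "graph": graph, "division_events": events,
              "n_local_minima": n_min}
    manifest = dict(scenario="organoid", mode=mode, t_G=t_G, P=P,
                    n_max=n_max, n0=n0, dt=dt, eta=eta, seed=seed,
                    t_relax=t_relax)
    return ScenarioResult("organoid", manifest, state, traj, extras)


def scenario_tube(lambda3: float, n: int = 1000, lambda2: float = 0.5,
                  pcp_in_plane: bool = False, t_end: float = 1000.0,
                  dt: float = 0.2, eta: float = 1e-4, seed: int = 0,
                  frame_stride: int | None = None,
                  metrics_stride: int | None = None) -> ScenarioResult:
    """Convergent-extension tube formation from a spherical lumen.

    Cells start on a hollow sphere with radial AB polarity and PCP
    whirling about the z axis; all cells share
    (l1, l2, l3) = (1 - lambda2 - lambda3, lambda2, lambda3).  PCP-driven
    intercalation elongates the lumen into a tube whose aspect ratio
    grows with lambda3.  With ``pcp_in_plane`` PCP is confined to the
    apical plane and cannot reorient AB polarity.
    """
    lambda1 = 1.0 - lambda2 - lambda3
    if lambda1 < 0 or lambda2 < 0 or lambda3 < 0:
        raise ValueError("lambda1 = 1 - lambda2 - lambda3 must be >= 0")
    rng = np.random.default_rng(seed)
    config = ModelConfig(dt=dt, eta=eta, seed=seed)
    state = make_hollow_sphere(n, pcp_whirl=True, rng=rng)
    state.lambdas[:] = (lambda1, lambda2, lambda3)
    state.pcp_in_plane_mask[:] = pcp_in_plane
    state, traj = run(state, config, int(round(t_end / dt)), rng=rng,
                      frame_stride=frame_stride,
                      metrics_stride=metrics_stride)
    semi_major, semi_minor = _metrics.tube_axes(state)
    extras = {"config": config, "semi_major": semi_major,
              "semi_minor": semi_minor}
    manifest = dict(scenario="tube", lambda3=lambda3, n=n, lambda2=lambda2,
                    pcp_in_plane=pcp_in_plane, t_end=t_end, dt=dt, eta=eta,
                    seed=seed)
    return ScenarioResult("tube", manifest, state, traj, extras)


def scenario_gastrulation(n: int = 600, k: float = 0.02,
                          sigma: float = 10.0, t_end: float = 3500.0,
                          dt: float = 0.2, eta: float = 1e-4, seed: int = 0,
                          pcp_on: bool = True, force_on: bool = True,
                          lambdas_lower=(0.5, 0.4, 0.1),
                          frame_stride: int | None = None,
                          sample_every: float = 20.0) -> ScenarioResult:
    """Sea-urchin-style gastrulation from a blastula.

    The lower third of a radially polarized hollow sphere acquires PCP
    whirling about the anterior-posterior (z) axis as a boundary
    condition — held azimuthal in the apical plane throughout the run,
    the way an organizer orients PCP — with polarity strengths
    ``lambdas_lower``; the remaining cells keep pure AB polarity.  An
    external bottle-cell force of strength ``k`` and Gaussian width
    ``sigma`` reorients the AB polarity of the lower cells near the
    axis, bending the bottom inward; PCP-driven convergent extension
    then elongates the invaginated cells into a tube that grows toward
    the top pole.  Controls: ``force_on=False`` (PCP alone exvaginates,
    the tube extending outside) and ``pcp_on=False`` (the force alone
    invaginates but the cavity stays round, no tube).

    ``extras['stages']`` records the detected stage times (flattening,
    invagination or exvagination, near-contact with the top pole),
    measured on the cells that start nearest the bottom pole.
    """
    if n < 500:
        raise ValueError("n must be >= 500")
    if abs(sum(lambdas_lower) - 1.0) > 1e-9 or min(lambdas_lower) < 0:
        raise ValueError("lambdas_lower must be a non-negative triple "
                         "summing to 1")
    rng = np.random.default_rng(seed)
    config = ModelConfig(dt=dt, eta=eta, seed=seed)
    state = make_hollow_sphere(n, pcp_whirl=True, rng=rng)
    state = apply_polarity_field(state, "radial_point", fix=False,
                                 center=np.zeros(3))
    z = state.positions[:, 2]
    order = np.argsort(z)
    lower = np.zeros(n, dtype=bool)
    lower[order[: n // 3]] = True
    l1, l2, l3 = lambdas_lower
    if not pcp_on:
        l1, l2, l3 = l1 + l3, l2, 0.0
    state.lambdas[lower] = (l1, l2, l3)
    state.lambdas[~lower] = (1.0, 0.0, 0.0)
    state.pcp_active_mask[:] = False
    state.pcp_active_mask[lower] = True
    state.pcp_in_plane_mask[lower] = True
    radius = float(np.linalg.norm(state.positions, axis=1).mean())
    apex = np.zeros(n, dtype=bool)  # cells starting nearest the bottom pole
    apex[order[: max(10, n // 20)]] = True
    top = np.zeros(n, dtype=bool)  # animal-pole cells (merge target)
    top[order[-max(10, n // 20):]] = True

    fields = ExternalFields(force_k=(k if force_on else 0.0),
                            force_sigma=sigma, force_mask=lower,
                            pcp_pin_mask=lower)
    stage_rows = []
    stride = max(1, int(round(sample_every / dt)))

    def stage_metrics(st, graph, cfg):
        com = st.positions.mean(axis=0)
        rel = st.positions - com
        r_all = np.linalg.norm(rel, axis=1).mean()
        r_apex = np.linalg.norm(rel[apex], axis=1).mean()
        d = (st.positions[apex][:, None, :] - st.positions[top][None, :, :])
        gap = float(np.linalg.norm(d, axis=2).min())
        row = {"time": st.time, "apex_radial_ratio": r_apex / r_all,
               "apex_top_gap": gap}
        stage_rows.append(row)
        return row

    state, traj = run(state, config, int(round(t_end / dt)), fields,
                      rng=rng, frame_stride=frame_stride,
                      metrics_stride=stride, metrics_fn=stage_metrics)
    stages = _detect_stages(stage_rows)
    graph = _graph(state, config)
    extras = {"config": config, "graph": graph, "stages": stages,
              "lower_mask": lower, "apex_mask": apex, "radius": radius}
    manifest = dict(scenario="gastrulation", n=n, k=k, sigma=sigma,
                    t_end=t_end, dt=dt, eta=eta, seed=seed, pcp_on=pcp_on,
                    force_on=force_on, lambdas_lower=tuple(lambdas_lower))
    return ScenarioResult("gastrulation", manifest, state, traj, extras)


def _detect_stages(rows: list[dict]) -> dict:
    """Threshold-based stage detection on the tracked bottom-pole cells.

    flattening: apex radial ratio below 0.95 (the cap has moved toward
    the center relative to the shell); invagination: below 0.8 (cap
    clearly inside); exvagination: above 1.1; reached_top: the nearest
    apex cell comes within 4 cell radii (two rest spacings, i.e. at
    most one intervening cell) of an animal-pole cell.  Times are the
    first crossing of each threshold.
    """
    stages: dict = {"flattening_time": None, "invagination_time": None,
                    "exvagination_time": None, "reached_top_time": None,
                    "min_top_gap": None, "final_apex_ratio": None}
    if not rows:
        return stages
    for row in rows:
        t, ratio, gap = row["time"], row["apex_radial_ratio"], row["apex_top_gap"]
        if stages["flattening_time"] is None and ratio < 0.95:
            stages["flattening_time"] = t
        if stages["invagination_time"] is None and ratio < 0.8:
            stages["invagination_time"] = t
        if stages["exvagination_time"] is None and ratio > 1.1:
            stages["exvagination_time"] = t
        if stages["reached_top_time"] is None and gap < 4.0:
            stages["reached_top_time"] = t
    stages["min_top_gap"] = min(r["apex_top_gap"] for r in rows)
    stages["final_apex_ratio"] = rows[-1]["apex_radial_ratio"]
    return stages
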
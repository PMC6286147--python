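"""Cell division and exponential growth schedules.

Growing organoids follow N(t) = n0 * exp(ln(2) * t / t_G) with
generation (doubling) time ``t_G``.  A division picks a mother uniformly
at random from the whole population and places a daughter half a cell
radius away in a random direction, inheriting the mother's polarity
vectors, strengths, and masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import ExternalFields, Trajectory, _sample_metrics, step
from .interactions import find_neighbors
from .state import CellState, ModelConfig


@dataclass
class GrowthSchedule:
    """Exponential growth from ``n0`` cells with doubling time
    ``generation_time`` until ``n_max`` cells."""

    n0: int = 200
    generation_time: float = 1000.0
    n_max: int = 8000

    def __post_init__(self):
        if self.n_max < self.n0:
            raise ValueError("n_max must be >= n0")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")

    def target_count(self, t: float) -> int:
        if np.isinf(self.generation_time):
            return self.n0
        n = self.n0 * np.exp(np.log(2.0) * t / self.generation_time)
        return int(min(np.floor(n), self.n_max))


def divide(state: CellState, mother: int,
           rng: np.random.Generator | None = None) -> CellState:
    """Append a daughter of cell ``mother`` half a cell radius away in a
    uniformly random direction; polarities, strengths, and masks are
    copied from the mother.  Returns a new, larger state."""
    n = state.n_cells
    if not 0 <= mother < n:
        raise IndexError(f"mother index {mother} out of range for {n} cells")
    rng = np.random.default_rng() if rng is None else rng
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    new_pos = state.positions[mother] + 0.5 * u
    return CellState(
        positions=np.vstack([state.positions, new_pos]),
        ab_polarity=np.vstack([state.ab_polarity,
                               state.ab_polarity[mother]]),
        pcp=np.vstack([state.pcp, state.pcp[mother]]),
        lambdas=np.vstack([state.lambdas, state.lambdas[mother]]),
        fixed_polarity_mask=np.append(state.fixed_polarity_mask,
                                      state.fixed_polarity_mask[mother]),
        pcp_in_plane_mask=np.append(state.pcp_in_plane_mask,
                                    state.pcp_in_plane_mask[mother]),
        pcp_active_mask=np.append(state.pcp_active_mask,
                                  state.pcp_active_mask[mother]),
        time=state.time,
    )


def growth_driver(state: CellState, schedule: GrowthSchedule,
                  config: ModelConfig,
                  fields: ExternalFields | None = None,
                  rng: np.random.Generator | None = None,
                  frame_stride: int | None = None,
                  metrics_stride: int | None = None,
                  metrics_fn=None,
                  ) -> tuple[CellState, Trajectory, pd.DataFrame]:
    """Integrate the dynamics while dividing cells to track the growth
    law; runs until the population reaches ``schedule.n_max``.

    Divisions happen between integration steps: whenever the current
    count falls below ``floor(N(t))``, uniformly random mothers divide
    until the counts match.  Returns the final state, the sampled
    trajectory, and a division-event table (time, mother, daughter,
    position).
    """
    if state.n_cells != schedule.n0:
        raise ValueError("state must start with schedule.n0 cells")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    fields = ExternalFields() if fields is None else fields
    traj = Trajectory()
    events = []
    k = 0
    graph = None
    while True:
        target = schedule.target_count(state.time)
        while state.n_cells < target:
            mother = int(rng.integers(state.n_cells))
            state = divide(state, mother, rng)
            graph = None  # invalidate: cell count changed
            events.append({"time": state.time, "mother": mother,
                           "daughter": state.n_cells - 1,
                           "x": state.positions[-1, 0],
                           "y": state.positions[-1, 1],
                           "z": state.positions[-1, 2]})
        if graph is None or k % config.graph_stride == 0:
            graph = find_neighbors(state.positions,
                                   mode=config.neighbor_mode,
                                   cutoff=config.cutoff,
                                   prefilter_k=config.prefilter_k)
        if metrics_stride and k % metrics_stride == 0:
            traj.records.append(_sample_metrics(state, graph, config,
                                                metrics_fn))
        if frame_stride and k % frame_stride == 0:
            traj.frames.append(state.copy())
            traj.frame_times.append(state.time)
        if state.n_cells >= schedule.n_max:
            break
        step(state, graph, config, fields, rng)
        k += 1
    cols = ["time", "mother", "daughter", "x", "y", "z"]
    return state, traj, pd.DataFrame(events, columns=cols)
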
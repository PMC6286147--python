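import numpy as np
import pytest

from polarsim import CellState, ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return ModelConfig(eta=0.0)


def random_unit(rng, n=1):
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v[0] if n == 1 else v


def make_pair_state(r, p_i, p_j, q_i=(0, 1, 0), q_j=(0, 1, 0),
                    lambdas=(1.0, 0.0, 0.0)):
    """Two cells on the x axis at separation r."""
    return CellState(
        positions=np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]),
        ab_polarity=np.array([p_i, p_j], dtype=float),
        pcp=np.array([q_i, q_j], dtype=float),
        lambdas=np.array([lambdas, lambdas], dtype=float),
        fixed_polarity_mask=np.zeros(2, dtype=bool),
        pcp_in_plane_mask=np.zeros(2, dtype=bool),
        pcp_active_mask=np.zeros(2, dtype=bool),
    )


def brute_force_line_of_sight(positions):
    """O(N^3) midpoint criterion: edge (i, j) iff every other cell is
    strictly farther than r_ij/2 from the pair midpoint."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            mid = 0.5 * (pos[i] + pos[j])
            half = 0.5 * np.linalg.norm(pos[i] - pos[j])
            d = np.linalg.norm(pos - mid, axis=1)
            d[i] = d[j] = np.inf
            if d.min() > half:
                edges.add((i, j))
    return edges
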
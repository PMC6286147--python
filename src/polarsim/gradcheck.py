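"""Finite-difference validation of the analytic pair gradients.

The pair potential composed with the coupling factors defines a scalar
function of the positions and (normalized) polarity vectors; its central
finite differences are the ground truth the analytic gradients must
match.  Polarity vectors are perturbed in raw Cartesian coordinates and
normalized inside the potential, which makes the numeric derivative the
tangential gradient the integrator uses.
"""

from __future__ import annotations

import numpy as np

from .interactions import pair_gradients
from .state import ModelConfig


def _pair_energy(ri, rj, pi_raw, pj_raw, qi_raw, qj_raw, li, lj, config,
                 ) -> float:
    pi = pi_raw / np.linalg.norm(pi_raw)
    pj = pj_raw / np.linalg.norm(pj_raw)
    qi = qi_raw / np.linalg.norm(qi_raw)
    qj = qj_raw / np.linalg.norm(qj_raw)
    dr = rj - ri
    r = np.linalg.norm(dr)
    rh = dr / r
    S1 = np.dot(np.cross(pi, rh), np.cross(pj, rh))
    S2 = np.dot(np.cross(pi, qi), np.cross(pj, qj))
    S3 = np.dot(np.cross(qi, rh), np.cross(qj, rh))
    l1, l2, l3 = 0.5 * (np.asarray(li) + np.asarray(lj))
    if config.angle_gate and np.dot(pi, pj) < 0:
        l1 = 0.0
    S = l1 * S1 + l2 * S2 + l3 * S3
    m = config.potential_exponent
    return float(np.exp(-(r ** m)) - S * np.exp(-((r / config.beta) ** m)))


def numeric_pair_gradients(ri, rj, pi, pj, qi, qj, li, lj, config,
                           h: float = 1e-6):
    """Central finite differences of the pair energy with respect to the
    position and both polarity vectors of cell i."""
    args = [np.asarray(a, dtype=float).copy()
            for a in (ri, rj, pi, pj, qi, qj)]
    grads = []
    for slot in (0, 2, 4):  # ri, pi, qi
        g = np.zeros(3)
        for c in range(3):
            plus = [a.copy() for a in args]
            minus = [a.copy() for a in args]
            plus[slot][c] += h
            minus[slot][c] -= h
            g[c] = (_pair_energy(*plus, li, lj, config)
                    - _pair_energy(*minus, li, lj, config)) / (2 * h)
        grads.append(g)
    return tuple(grads)


def random_pair_configuration(rng: np.random.Generator):
    """A random interacting pair: separation in (0.8, 4), random unit
    polarities, random simplex lambda triples."""
    ri = rng.standard_normal(3)
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    rj = ri + (0.8 + 3.2 * rng.random()) * d
    units = rng.standard_normal((4, 3))
    units /= np.linalg.norm(units, axis=1, keepdims=True)
    lams = rng.dirichlet(np.ones(3), size=2)
    return ri, rj, units[0], units[1], units[2], units[3], lams[0], lams[1]


def max_relative_gradient_error(n_configs: int = 200, seed: int = 0,
                                config: ModelConfig | None = None,
                                h: float = 1e-6) -> float:
    """Worst relative error between analytic and finite-difference
    gradients over random pair configurations (relative to the larger of
    the gradient norm and 1e-8)."""
    rng = np.random.default_rng(seed)
    config = ModelConfig() if config is None else config
    worst = 0.0
    for _ in range(n_configs):
        ri, rj, pi, pj, qi, qj, li, lj = random_pair_configuration(rng)
        pair = pair_gradients(ri, rj, pi, pj, qi, qj, (li, lj), config)
        numeric = numeric_pair_gradients(ri, rj, pi, pj, qi, qj, li, lj,
                                         config, h=h)
        for a, g in zip((pair.dV_dri, pair.dV_dpi, pair.dV_dqi), numeric):
            denom = max(np.linalg.norm(g), 1e-8)
            worst = max(worst, np.linalg.norm(a - g) / denom)
    return worst
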
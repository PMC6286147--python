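"""Unit and property tests for the pair potential, coupling factors,
neighbor rule, and analytic gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

import polarsim as ps
from polarsim.gradcheck import numeric_pair_gradients, random_pair_configuration
from polarsim.state import ModelConfig

from conftest import brute_force_line_of_sight, random_unit

Z = np.array([0.0, 0.0, 1.0])
X = np.array([1.0, 0.0, 0.0])
Y = np.array([0.0, 1.0, 0.0])


unit_vectors = st.builds(
    lambda seed: random_unit(np.random.default_rng(seed)),
    st.integers(0, 2**31 - 1))


class TestCouplingFactors:
    @pytest.mark.parametrize("pi,pj,expected", [
        (Z, Z, 1.0),            # apical sides adjacent: maximal attraction
        (Z, -Z, -1.0),          # apical next to basal: maximal repulsion
        (X, Z, 0.0),            # polarity parallel to separation
        (X, Y, 0.0),
    ])
    def test_s1_reference_cases(self, pi, pj, expected):
        assert ps.polarity_factor_s1(pi, pj, X) == pytest.approx(expected)

    def test_s1_symmetric_under_pair_exchange(self, rng):
        for _ in range(20):
            pi, pj, r = (random_unit(rng) for _ in range(3))
            assert ps.polarity_factor_s1(pi, pj, r) == pytest.approx(
                ps.polarity_factor_s1(pj, pi, -r), abs=1e-12)

    def test_s2_orthonormal_frames(self):
        assert ps.polarity_factor_s2(Z, X, Z, X) == pytest.approx(1.0)
        assert ps.polarity_factor_s2(Z, Z, Z, X) == pytest.approx(0.0)

    @pytest.mark.parametrize("qi,qj,expected", [
        (Y, Y, 1.0), (Y, -Y, -1.0),
    ])
    def test_s3_reference_cases(self, qi, qj, expected):
        assert ps.polarity_factor_s3(qi, qj, X) == pytest.approx(expected)

    def test_factors_match_quadruple_product_identity(self, rng):
        # Lagrange identity (a x c).(b x c) = (a.b) - (a.c)(b.c) for unit c
        for _ in range(20):
            pi, pj, qi, qj, r = (random_unit(rng) for _ in range(5))
            assert ps.polarity_factor_s1(pi, pj, r) == pytest.approx(
                pi @ pj - (pi @ r) * (pj @ r), abs=1e-12)
            assert ps.polarity_factor_s2(pi, qi, pj, qj) == pytest.approx(
                (pi @ pj) * (qi @ qj) - (pi @ qj) * (qi @ pj), abs=1e-12)
            assert ps.polarity_factor_s3(qi, qj, r) == pytest.approx(
                qi @ qj - (qi @ r) * (qj @ r), abs=1e-12)

    def test_non_unit_input_rejected(self):
        with pytest.raises(ValueError):
            ps.polarity_factor_s1(2 * Z, Z, X)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(unit_vectors, unit_vectors, unit_vectors, unit_vectors)
    def test_factors_bounded(self, pi, pj, qi, qj):
        r = np.cross(pi, qi)
        if np.linalg.norm(r) < 1e-6:
            r = Y
        r = r / np.linalg.norm(r)
        for s in (ps.polarity_factor_s1(pi, pj, r),
                  ps.polarity_factor_s2(pi, qi, pj, qj),
                  ps.polarity_factor_s3(qi, qj, r)):
            assert -1.0 - 1e-12 <= s <= 1.0 + 1e-12


class TestCoupling:
    def test_pure_ab(self):
        assert ps.coupling(0.7, 0.1, 0.2, (1, 0, 0), (1, 0, 0)) == 0.7

    def test_mixed_cells_use_mean_strengths(self):
        # effective lambdas are pairwise means: 0.5*1 + 0.5*1 = 1
        assert ps.coupling(1.0, 1.0, 0.0, (1, 0, 0), (0, 1, 0)) == pytest.approx(1.0)
        assert ps.coupling(1.0, 0.0, 0.0, (1, 0, 0), (0, 1, 0)) == pytest.approx(0.5)

    def test_angle_gate_zeroes_ab_term(self):
        s = ps.coupling(1.0, 0.0, 0.0, (1, 0, 0), (1, 0, 0),
                        angle_gate=True, p_dot=-0.1)
        assert s == 0.0
        s = ps.coupling(1.0, 0.0, 0.0, (1, 0, 0), (1, 0, 0),
                        angle_gate=True, p_dot=0.1)
        assert s == 1.0

    def test_invalid_lambdas_rejected(self):
        with pytest.raises(ValueError):
            ps.coupling(1, 0, 0, (0.5, 0.4, 0.2), (1, 0, 0))


class TestPairPotential:
    def test_reference_value(self):
        # exp(-2) - exp(-0.4), evaluated at high precision
        assert ps.pair_potential(2.0, 1.0, 5.0) == pytest.approx(
            -0.5349847627990266, abs=1e-12)

    def test_vanishes_at_infinity(self):
        assert ps.pair_potential(100.0, 0.0) == pytest.approx(0.0, abs=1e-40)
        assert ps.pair_potential(60.0, 1.0) == pytest.approx(0.0, abs=1e-5)

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            ps.pair_potential(0.0, 1.0)
        with pytest.raises(ValueError):
            ps.pair_potential(-1.0, 1.0)

    def test_quartic_variant_shape(self):
        # quartic variant: same repulsion/attraction structure
        r = ps.equilibrium_distance(1.0, 5.0, exponent=4)
        v = ps.pair_potential(r, 1.0, 5.0, exponent=4)
        assert v < 0
        eps = 1e-5
        assert ps.pair_potential(r + eps, 1.0, 5.0, 4) > v
        assert ps.pair_potential(r - eps, 1.0, 5.0, 4) > v


class TestEquilibriumDistance:
    @pytest.mark.parametrize("S", [0.25, 0.5, 1.0])
    @pytest.mark.parametrize("beta", [3.0, 5.0])
    def test_closed_form_matches_numeric_argmin(self, S, beta):
        # stationarity located from central differences of the potential
        h = 1e-5
        dV = lambda r: (ps.pair_potential(r + h, S, beta)
                        - ps.pair_potential(r - h, S, beta)) / (2 * h)
        root = brentq(dV, 0.1, 30.0, xtol=1e-12)
        assert ps.equilibrium_distance(S, beta) == pytest.approx(
            root, abs=1e-8)

    def test_aligned_pair_rests_at_two_cell_radii(self):
        r = ps.equilibrium_distance(1.0, 5.0)
        assert r == pytest.approx(2.0118, abs=5e-5)
        assert round(r) == 2

    def test_reference_values(self):
        assert ps.equilibrium_distance(5.0, 5.0) == pytest.approx(0.0)
        assert ps.equilibrium_distance(0.5, 5.0) == pytest.approx(
            2.8782, abs=5e-5)

    def test_no_minimum_without_attraction(self):
        with pytest.raises(ValueError):
            ps.equilibrium_distance(0.0)
        with pytest.raises(ValueError):
            ps.equilibrium_distance(-1.0)


class TestNeighborRule:
    def test_two_cells_always_interact(self):
        g = ps.find_neighbors(np.array([[0.0, 0, 0], [10.0, 0, 0]]))
        assert g.edge_set() == {(0, 1)}

    def test_collinear_middle_cell_blocks(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
        assert ps.find_neighbors(pos).edge_set() == {(0, 1), (1, 2)}

    def test_midpoint_tie_blocks(self):
        # third cell exactly at r_ij/2 from the midpoint: conservative block
        pos = np.array([[0.0, 0, 0], [4.0, 0, 0], [2.0, 2.0, 0]])
        assert (0, 1) not in ps.find_neighbors(pos).edge_set()

    def test_matches_brute_force_on_random_clouds(self, rng):
        for _ in range(8):
            n = int(rng.integers(5, 55))
            pos = rng.random((n, 3)) * 6.0
            assert ps.find_neighbors(pos).edge_set() == \
                brute_force_line_of_sight(pos)

    def test_coincident_positions_rejected(self):
        pos = np.zeros((3, 3))
        pos[2, 0] = 1.0
        with pytest.raises(ValueError):
            ps.find_neighbors(pos)

    def test_prefilter_does_not_change_result(self, rng):
        pos = rng.random((50, 3)) * 5.0
        full = ps.find_neighbors(pos, prefilter_k=49).edge_set()
        assert ps.find_neighbors(pos, prefilter_k=100).edge_set() == full

    def test_voronoi_cutoff_mode(self, rng):
        pos = rng.random((30, 3)) * 6.0
        g = ps.find_neighbors(pos, mode="voronoi_cutoff", cutoff=3.0)
        d = np.linalg.norm(pos[g.edges[:, 0]] - pos[g.edges[:, 1]], axis=1)
        assert (d <= 3.0).all()
        assert len(g.edges) > 0

    def test_neighbor_exchange_logging(self, rng):
        pos = rng.random((30, 3)) * 5.0
        g0 = ps.find_neighbors(pos)
        moved = pos.copy()
        moved[0] += 1.5
        g1 = ps.find_neighbors(moved)
        gained, lost = g0.exchanges(g1)
        assert gained == g1.edge_set() - g0.edge_set()
        assert lost == g0.edge_set() - g1.edge_set()
        assert g0.exchanges(g0) == (set(), set())

    def test_graph_is_symmetric_without_self_edges(self, rng):
        pos = rng.random((40, 3)) * 5.0
        g = ps.find_neighbors(pos)
        assert (g.edges[:, 0] < g.edges[:, 1]).all()
        assert g.degree.sum() == 2 * len(g.edges)


class TestPairGradients:
    def _config(self, **kw):
        return ModelConfig(eta=0.0, **kw)

    def test_matches_finite_differences(self, rng):
        config = self._config()
        worst = 0.0
        for _ in range(60):
            ri, rj, pi, pj, qi, qj, li, lj = random_pair_configuration(rng)
            pair = ps.pair_gradients(ri, rj, pi, pj, qi, qj, (li, lj), config)
            num = numeric_pair_gradients(ri, rj, pi, pj, qi, qj, li, lj,
                                         config)
            for a, g in zip((pair.dV_dri, pair.dV_dpi, pair.dV_dqi), num):
                worst = max(worst, np.linalg.norm(a - g) /
                            max(np.linalg.norm(g), 1e-8))
        assert worst < 1e-6

    def test_quartic_gradients_match_finite_differences(self, rng):
        config = self._config(potential_exponent=4)
        for _ in range(20):
            ri, rj, pi, pj, qi, qj, li, lj = random_pair_configuration(rng)
            pair = ps.pair_gradients(ri, rj, pi, pj, qi, qj, (li, lj), config)
            num = numeric_pair_gradients(ri, rj, pi, pj, qi, qj, li, lj,
                                         config)
            for a, g in zip((pair.dV_dri, pair.dV_dpi, pair.dV_dqi), num):
                assert np.linalg.norm(a - g) <= 1e-6 * max(
                    np.linalg.norm(g), 1e-8)

    def test_force_antisymmetry(self, rng):
        config = self._config()
        for _ in range(20):
            ri, rj, pi, pj, qi, qj, li, lj = random_pair_configuration(rng)
            ij = ps.pair_gradients(ri, rj, pi, pj, qi, qj, (li, lj), config)
            ji = ps.pair_gradients(rj, ri, pj, pi, qj, qi, (lj, li), config)
            np.testing.assert_allclose(ij.dV_dri, -ji.dV_dri, atol=1e-12)
            assert ij.V == pytest.approx(ji.V, abs=1e-12)

    def test_stationary_at_equilibrium_distance(self):
        config = self._config()
        r = ps.equilibrium_distance(1.0, 5.0)
        pair = ps.pair_gradients(
            np.zeros(3), np.array([r, 0, 0]), Z, Z, Y, Y,
            ((1, 0, 0), (1, 0, 0)), config)
        assert np.linalg.norm(pair.dV_dri) < 1e-9
        assert pair.V == pytest.approx(-0.5349922439811376, abs=1e-9)

    def test_rotation_equivariance(self, rng):
        config = self._config()
        rot = Rotation.random(random_state=7).as_matrix()
        for _ in range(10):
            ri, rj, pi, pj, qi, qj, li, lj = random_pair_configuration(rng)
            a = ps.pair_gradients(ri, rj, pi, pj, qi, qj, (li, lj), config)
            b = ps.pair_gradients(rot @ ri, rot @ rj, rot @ pi, rot @ pj,
                                  rot @ qi, rot @ qj, (li, lj), config)
            assert b.V == pytest.approx(a.V, abs=1e-9)
            np.testing.assert_allclose(b.dV_dri, rot @ a.dV_dri, atol=1e-9)
            np.testing.assert_allclose(b.dV_dpi, rot @ a.dV_dpi, atol=1e-9)
            np.testing.assert_allclose(b.dV_dqi, rot @ a.dV_dqi, atol=1e-9)

    def test_coincident_cells_rejected(self):
        with pytest.raises(ValueError):
            ps.pair_gradients(np.zeros(3), np.zeros(3), Z, Z, Y, Y,
                              ((1, 0, 0), (1, 0, 0)), self._config())

    def test_vectorized_kernel_matches_reference(self, rng):
        config = self._config(angle_gate=True)
        n = 30
        pos = rng.random((n, 3)) * 5.0
        p = random_unit(rng, n)
        q = random_unit(rng, n)
        lam = rng.dirichlet(np.ones(3), n)
        in_plane = rng.random(n) < 0.3
        graph = ps.find_neighbors(pos)
        gr, gp, gq, en = ps.system_gradients(pos, p, q, lam, graph, config,
                                             pcp_in_plane=in_plane)
        GR, GP, GQ = (np.zeros((n, 3)) for _ in range(3))
        EN = np.zeros(n)
        for i, j in graph.edges:
            a = ps.pair_gradients(pos[i], pos[j], p[i], p[j], q[i], q[j],
                                  (lam[i], lam[j]), config,
                                  in_plane_i=in_plane[i])
            b = ps.pair_gradients(pos[j], pos[i], p[j], p[i], q[j], q[i],
                                  (lam[j], lam[i]), config,
                                  in_plane_i=in_plane[j])
            GR[i] += a.dV_dri
            GP[i] += a.dV_dpi
            GQ[i] += a.dV_dqi
            EN[i] += a.V
            GR[j] += b.dV_dri
            GP[j] += b.dV_dpi
            GQ[j] += b.dV_dqi
            EN[j] += b.V
        np.testing.assert_allclose(gr, GR, atol=1e-12)
        np.testing.assert_allclose(gp, GP, atol=1e-12)
        np.testing.assert_allclose(gq, GQ, atol=1e-12)
        np.testing.assert_allclose(en, EN, atol=1e-12)
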
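"""Core model: topologies, kinetics, Jacobian, uniform state."""

import numpy as np
import pytest

from turingcells.model import (
    ArrayTopology,
    CellArrayState,
    KineticParams,
    apply_permutation,
    automorphisms,
    build_topology,
    jac_z,
    jacobian,
    mode_matrix,
    rhs,
    rhs_param_deriv,
    rhs_z,
    single_cell_jacobian,
    uniform_steady_state,
)


class TestKineticParams:
    def test_defaults_are_the_standard_setting(self):
        p = KineticParams()
        assert (p.phi, p.nu, p.L, p.n, p.M, p.k_s) == (1.0, 1.84, 5e6, 4, 10.0, 0.06)

    @pytest.mark.parametrize("bad", [
        {"nu": -1.0}, {"sigma_M": 0.0}, {"n": 0}, {"n": 2.5},
        {"q": -0.1}, {"k_ADP": -1e-9}, {"L": 0.0},
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            KineticParams(**bad)


class TestTopology:
    @pytest.mark.parametrize("kind,N,edges", [
        ("linear", 4, {(1, 2), (2, 3), (3, 4)}),
        ("cyclic", 4, {(1, 2), (2, 3), (3, 4), (1, 4)}),
        ("linear", 1, set()),
        ("t_shaped", 4, {(1, 2), (2, 3), (2, 4)}),
    ])
    def test_builtin_edge_sets(self, kind, N, edges):
        top = build_topology(kind, N)
        assert set(top.edges()) == edges
        assert np.allclose(top.delta, top.delta.T)
        assert np.all(np.diag(top.delta) == 0)

    @pytest.mark.parametrize("kind,N", [("t_shaped", 5), ("cyclic", 2),
                                        ("hexagonal", 4), ("linear", 0)])
    def test_invalid_combinations_rejected(self, kind, N):
        with pytest.raises(ValueError):
            build_topology(kind, N)

    @pytest.mark.parametrize("kind,N,order", [
        ("cyclic", 4, 8),    # dihedral group of the 4-cycle
        ("linear", 4, 2),    # identity + reversal
        ("t_shaped", 4, 6),  # permutations of the three leaves
        ("cyclic", 3, 6),
    ])
    def test_automorphism_group_orders(self, kind, N, order):
        assert len(automorphisms(build_topology(kind, N))) == order

    def test_automorphisms_form_a_group(self, random_fixtures):
        for fx in random_fixtures:
            top = ArrayTopology(N=fx["N"], delta=np.array(fx["delta"]))
            auts = {tuple(a) for a in automorphisms(top)}
            assert tuple(range(top.N)) in auts
            for a in auts:
                for b in auts:
                    composed = tuple(a[b[i]] for i in range(top.N))
                    assert composed in auts


class TestRhs:
    def test_origin_gives_pure_uptake(self, gate_params, cyclic3):
        st = CellArrayState(x=np.zeros(3), y=np.zeros(3))
        dz = rhs(st, gate_params, cyclic3)
        assert np.allclose(dz[:3], gate_params.nu)
        assert np.allclose(dz[3:], 0.0)

    def test_identical_cells_decouple(self, gate_params, cyclic3, single_cell):
        st1 = CellArrayState(x=[12.0], y=[25.0])
        d1 = rhs(st1, gate_params, single_cell)
        st3 = CellArrayState(x=np.full(3, 12.0), y=np.full(3, 25.0))
        d3 = rhs(st3, gate_params, cyclic3)
        assert np.allclose(d3, np.concatenate([np.full(3, d1[0]), np.full(3, d1[1])]))

    def test_algebraic_identity_of_the_kinetics(self, gate_params, two_cell):
        # phi*(dx - coupling_x - p) + (dy - coupling_y) = phi*nu - k_s*y
        rng = np.random.default_rng(4)
        p = gate_params
        decoupled = p.replace(k_ADP=0.0)
        for _ in range(50):
            z = rng.uniform(0, 120, 4)
            dz = rhs_z(z, decoupled, two_cell)
            lhs = p.phi * dz[:2] + dz[2:]
            assert np.allclose(lhs, p.phi * p.nu - p.k_s * z[2:], rtol=1e-12)

    def test_coupling_conserves_total_mass(self, gate_params, random_fixtures):
        rng = np.random.default_rng(5)
        for fx in random_fixtures:
            top = ArrayTopology(N=fx["N"], delta=np.array(fx["delta"]))
            p = KineticParams(**fx["params"])
            z = rng.uniform(0, 100, 2 * top.N)
            coupling = rhs_z(z, p, top) - rhs_z(z, p.replace(k_ADP=0.0), top)
            assert abs(coupling[:top.N].sum()) < 1e-9
            assert abs(coupling[top.N:].sum()) < 1e-9

    def test_equivariance_under_automorphisms(self, random_fixtures):
        rng = np.random.default_rng(6)
        for fx in random_fixtures:
            top = ArrayTopology(N=fx["N"], delta=np.array(fx["delta"]))
            p = KineticParams(**fx["params"])
            z = rng.uniform(0, 100, 2 * top.N)
            base = rhs_z(z, p, top)
            for perm in automorphisms(top):
                assert np.allclose(rhs_z(apply_permutation(z, perm), p, top),
                                   apply_permutation(base, perm), rtol=1e-12)

    def test_negative_concentrations_rejected(self, gate_params, two_cell):
        st = CellArrayState(x=[1.0, -0.5], y=[1.0, 1.0])
        with pytest.raises(ValueError):
            rhs(st, gate_params, two_cell)


class TestJacobian:
    def test_matches_finite_differences(self, gate_params, cyclic3):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(100):
            z = rng.uniform(0.1, 120, 6)
            J = jac_z(z, gate_params, cyclic3)
            Jfd = np.empty_like(J)
            for j in range(6):
                h = 1e-6 * max(1.0, abs(z[j]))
                dz = np.zeros(6)
                dz[j] = h
                Jfd[:, j] = (rhs_z(z + dz, gate_params, cyclic3)
                             - rhs_z(z - dz, gate_params, cyclic3)) / (2 * h)
            worst = max(worst, np.abs(J - Jfd).max() / np.abs(J).max())
        assert worst < 1e-6

    def test_uncoupled_array_is_block_diagonal(self, gate_params, cyclic3):
        p = gate_params.replace(k_ADP=0.0)
        z = np.array([10.0, 20.0, 30.0, 15.0, 25.0, 35.0])
        J = jac_z(z, p, cyclic3)
        for i in range(3):
            cell = single_cell_jacobian(z[i], z[3 + i], p)
            assert np.allclose(J[np.ix_([i, 3 + i], [i, 3 + i])], cell)
        mask = np.ones((6, 6), bool)
        for i in range(3):
            mask[np.ix_([i, 3 + i], [i, 3 + i])] = False
        assert np.allclose(J[mask], 0.0)

    def test_uniform_state_spectrum_decomposes_over_modes(self, gate_params, cyclic3):
        xs, ys = uniform_steady_state(gate_params)
        z = np.concatenate([np.full(3, xs), np.full(3, ys)])
        full = np.sort_complex(np.linalg.eigvals(jac_z(z, gate_params, cyclic3)))
        mus = np.linalg.eigvalsh(cyclic3.laplacian)
        modes = np.sort_complex(np.concatenate(
            [np.linalg.eigvals(mode_matrix(mu, gate_params, xs, ys)) for mu in mus]))
        assert np.allclose(full, modes, atol=1e-8)

    def test_parameter_derivatives_match_finite_differences(self, gate_params, two_cell):
        rng = np.random.default_rng(8)
        z = rng.uniform(1, 80, 4)
        for name in ("sigma_M", "sigma_inh", "k_ADP", "q"):
            v = getattr(gate_params, name)
            h = 1e-6 * max(v, 1.0)
            num = (rhs_z(z, gate_params.replace(**{name: v + h}), two_cell)
                   - rhs_z(z, gate_params.replace(**{name: v - h}), two_cell)) / (2 * h)
            ana = rhs_param_deriv(z, gate_params, two_cell, name)
            assert np.allclose(num, ana, rtol=1e-5, atol=1e-8)


class TestUniformSteadyState:
    def test_adp_level_closed_form(self, gate_params):
        xs, ys = uniform_steady_state(gate_params)
        assert ys == pytest.approx(30.6667, abs=5e-5)
        assert abs(float(rhs_z(np.array([xs, ys]), gate_params,
                               ArrayTopology(N=1, delta=np.zeros((1, 1)))).max())) < 1e-9

    def test_adp_level_independent_of_rate_coefficients(self, gate_params):
        ys_ref = uniform_steady_state(gate_params)[1]
        for si in (5.0, 20.0, 35.0, 60.0):
            for sM in (80.0, 100.0, 150.0):
                p = gate_params.replace(sigma_inh=si, sigma_M=sM)
                assert uniform_steady_state(p)[1] == ys_ref

    def test_atp_level_is_the_unique_kinetics_root(self, gate_params):
        from turingcells.model import fx_cell

        xs, ys = uniform_steady_state(gate_params)
        grid = np.linspace(0.0, 10 * xs, 4001)
        vals = fx_cell(grid, ys, gate_params)
        sign_changes = np.sum(np.sign(vals[:-1]) != np.sign(vals[1:]))
        assert sign_changes == 1

    def test_missing_state_reported(self):
        # at sigma_M=10 the uptake exceeds the maximal autocatalytic rate
        # once sigma_inh is large enough: no uniform stationary state
        with pytest.raises(ValueError, match="no uniform stationary state"):
            uniform_steady_state(KineticParams(sigma_M=10.0, sigma_inh=20.0))

    def test_fixture_uniform_states_verify(self, random_fixtures):
        for fx in random_fixtures:
            p = KineticParams(**fx["params"])
            xs, ys = uniform_steady_state(p)
            assert ys == pytest.approx(p.phi * p.nu / p.k_s, rel=1e-12)
            assert xs == pytest.approx(fx["uniform_state"]["x"], rel=1e-9)
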
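"""Branch tracing, bifurcation detection, two-parameter curves, region maps."""

import numpy as np
import pytest

from turingcells.continuation import (
    Branch,
    detect_bifurcations,
    region_map,
    secondary_hopf_curve,
    solution_diagram,
    switch_branch,
    trace_branch,
    uniform_mode_curve,
)
from turingcells.model import (
    CellArrayState,
    build_topology,
    mode_matrix,
    single_cell_jacobian,
    uniform_steady_state,
)
from turingcells.steady_states import enumerate_states, newton_solve


def _uniform_seed(params, topology):
    xs, ys = uniform_steady_state(params)
    z = np.concatenate([np.full(topology.N, xs), np.full(topology.N, ys)])
    return newton_solve(CellArrayState.from_z(z), params, topology)


def _two_sided(seed, params, topology, name, prange, **kw):
    b_up = trace_branch(seed, params, topology, name, prange, direction=+1, **kw)
    b_dn = trace_branch(seed, params, topology, name, prange, direction=-1, **kw)
    return Branch(name, b_dn.points[::-1] + b_up.points[1:], params, topology)


@pytest.fixture(scope="module")
def uniform_branch_cyclic3(gate_params, cyclic3):
    seed = _uniform_seed(gate_params, cyclic3)
    b = _two_sided(seed, gate_params, cyclic3, "sigma_inh", (5.0, 98.0),
                   max_step=0.05)
    detect_bifurcations(b)
    return b


class TestUniformBranch:
    def test_adp_level_constant_along_the_branch(self, uniform_branch_cyclic3, gate_params):
        ys = uniform_steady_state(gate_params)[1]
        for pt in uniform_branch_cyclic3.points:
            assert np.allclose(pt.z[3:], ys, atol=1e-8)

    def test_exactly_two_primary_hopf_points(self, uniform_branch_cyclic3):
        hopfs = [bp for bp in uniform_branch_cyclic3.bifurcations if bp.kind == "hopf"]
        assert len(hopfs) == 2
        lo, hi = sorted(bp.param for bp in hopfs)
        assert 15.0 < lo < 20.0 and 90.0 < hi < 98.0

    def test_hopf_locations_match_dense_eigenvalue_scan(self, uniform_branch_cyclic3,
                                                        gate_params):
        # independent oracle: trace of the single-cell Jacobian on a fine grid
        hopfs = sorted(bp.param for bp in uniform_branch_cyclic3.bifurcations
                       if bp.kind == "hopf")
        from scipy.optimize import brentq

        def tr(si):
            p = gate_params.replace(sigma_inh=si)
            xs, ys = uniform_steady_state(p)
            J = single_cell_jacobian(xs, ys, p)
            return J[0, 0] + J[1, 1]

        grid = np.linspace(6.0, 97.0, 400)
        vals = [tr(v) for v in grid]
        roots = [brentq(tr, a, b, xtol=1e-10)
                 for a, b, va, vb in zip(grid, grid[1:], vals, vals[1:]) if va * vb < 0]
        assert len(roots) == 2
        for ours, oracle in zip(hopfs, sorted(roots)):
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_branch_points_resolve_to_nonuniform_states(self, uniform_branch_cyclic3,
                                                        gate_params, cyclic3):
        bps = [bp for bp in uniform_branch_cyclic3.bifurcations
               if bp.kind == "branch_point"]
        assert bps
        par = gate_params.replace(sigma_inh=bps[0].param)
        switched = switch_branch(bps[0], par, cyclic3)
        assert switched
        for s in switched:
            assert s.symmetry != "uniform"
            assert s.residual < 1e-10

    def test_branch_points_re_solve_under_newton(self, uniform_branch_cyclic3,
                                                 gate_params, cyclic3):
        for pt in uniform_branch_cyclic3.points[:: len(uniform_branch_cyclic3.points) // 15]:
            p = gate_params.replace(sigma_inh=pt.param)
            st = newton_solve(CellArrayState.from_z(pt.z * 1.001), p, cyclic3)
            assert np.abs(st.z - pt.z).max() < 1e-8 * max(1.0, np.abs(pt.z).max())


class TestPrimaryHopfCurves:
    def test_uniform_hopf_independent_of_coupling(self, gate_params, cyclic3):
        """The uniform-mode Hopf loci are two k_ADP-independent vertical lines."""
        curve = uniform_mode_curve(gate_params, cyclic3, "hopf",
                                   ("sigma_inh", "k_ADP"),
                                   ((5.0, 98.0), (0.01, 0.3)), mu=0.0, n_grid=40)
        assert len(curve.points) >= 60
        values = np.sort(curve.points[:, 0])
        lines = np.split(values, [np.argmax(np.diff(values)) + 1])
        assert len(lines) == 2
        for line in lines:
            assert np.ptp(line) < 1e-8  # vertical in the plane

    def test_uniform_hopf_independent_of_q(self, gate_params, cyclic3):
        a = uniform_mode_curve(gate_params, cyclic3, "hopf",
                               ("sigma_inh", "q"), ((5.0, 98.0), (1.0, 100.0)),
                               mu=0.0, n_grid=25)
        vals = np.sort(np.unique(np.round(a.points[:, 0], 8)))
        assert len(vals) == 2


class TestSymmetryBreakingOnset:
    def test_no_branch_point_on_stable_uniform_branch_at_q1(self, gate_params, cyclic3):
        # q <= 1: symmetry breaking only where the uniform state is already
        # unstable (inside the Hopf window)
        curve = uniform_mode_curve(gate_params, cyclic3, "branch_point",
                                   ("sigma_inh", "k_ADP"),
                                   ((5.0, 98.0), (0.05, 0.2)), mu=3.0, n_grid=30)
        hopf_lo, hopf_hi = 17.808, 95.391
        for si, _k in curve.points:
            assert hopf_lo < si < hopf_hi

    def test_spontaneous_turing_onset_at_q100(self):
        # q = 100, sigma_M = 10: branch points exist where the uniform state
        # is stable (below the Hopf window) -- spontaneous pattern onset
        from turingcells.model import KineticParams

        p = KineticParams(sigma_M=10.0, sigma_inh=2.0, q=100.0, k_ADP=0.01)
        top = build_topology("linear", 4)
        mus = np.linalg.eigvalsh(top.laplacian)
        found_stable_onset = False
        curve = None
        for mu in mus[1:]:
            curve = uniform_mode_curve(p, top, "branch_point",
                                       ("sigma_inh", "k_ADP"),
                                       ((0.2, 12.0), (5e-4, 0.05)), float(mu),
                                       n_grid=40)
            for si, k in curve.points:
                pp = p.replace(sigma_inh=si, k_ADP=k)
                xs, ys = uniform_steady_state(pp)
                uniform_mode = np.linalg.eigvals(mode_matrix(0.0, pp, xs, ys))
                if uniform_mode.real.max() < 0:
                    found_stable_onset = True
        assert found_stable_onset


class TestSecondaryHopf:
    def test_stability_boundary_of_the_symmetric_triplet(self, gate_params, cyclic3):
        seed = [s for s in enumerate_states(gate_params, cyclic3, seed=0, n_starts=256)
                if s.stable and s.symmetry == "symmetric_nonuniform"][0]
        curve = secondary_hopf_curve(gate_params, cyclic3, seed,
                                     ("sigma_M", "sigma_inh"), (40.0, 140.0),
                                     np.array([35.0]), p1_step=2.0)
        assert len(curve.points) == 1
        sigma_M_hopf = curve.points[0, 0]
        # dense-scan oracle: track the state on a fine sigma_M grid
        z = seed.z.copy()
        prev_stable = None
        crossing = None
        for sM in np.arange(100.0, 60.0, -0.25):
            st = newton_solve(CellArrayState.from_z(z),
                              gate_params.replace(sigma_M=float(sM)), cyclic3)
            z = st.z
            if prev_stable is True and not st.stable:
                crossing = sM
                break
            prev_stable = st.stable
        assert crossing is not None
        assert sigma_M_hopf == pytest.approx(crossing, abs=0.3)


class TestRegionMap:
    def test_labels_match_branch_collected_states(self, gate_params, cyclic3):
        """(m, n) from multistart enumeration vs states read off continuation
        branches of the solution diagram, at nodes along one sigma_M column."""
        nodes = np.linspace(28.0, 44.0, 10)
        labels = region_map(("sigma_inh", "sigma_M"),
                            (nodes, np.array([100.0])), gate_params, cyclic3,
                            n_starts=384, seed=1)
        branches = solution_diagram(gate_params, cyclic3, "sigma_inh",
                                    (24.0, 50.0), max_step=0.05)
        agreement = 0
        from turingcells.model import apply_permutation, automorphisms

        auts = automorphisms(cyclic3)
        for lab in labels:
            collected = []
            for b in branches:
                pv = b.param_values
                zs = b.states()
                hits = np.where(np.sign(pv[:-1] - lab.p1)
                                != np.sign(pv[1:] - lab.p1))[0]
                for i in hits:
                    w = (lab.p1 - pv[i]) / (pv[i + 1] - pv[i])
                    z = (1 - w) * zs[i] + w * zs[i + 1]
                    st = newton_solve(CellArrayState.from_z(z),
                                      gate_params.replace(sigma_inh=lab.p1), cyclic3)
                    collected.append(st.z)
            # close under the automorphism group and deduplicate
            uniq = []
            scale = max(np.abs(np.array(collected)).max(), 1.0)
            for z in collected:
                for perm in auts:
                    pz = apply_permutation(z, perm)
                    if not any(np.abs(pz - u).max() < 1e-5 * scale for u in uniq):
                        uniq.append(pz)
            if len(uniq) == lab.m:
                agreement += 1
        assert agreement >= 0.95 * len(labels)
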
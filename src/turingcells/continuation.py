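"""Continuation of stationary states and bifurcation curves.

One-parameter branches are traced by pseudo-arclength predictor--corrector
continuation in any of the four free parameters (sigma_M, sigma_inh,
k_ADP, q), with detection of folds, Hopf points and symmetry-breaking
branch points, and branch switching at the latter.

Two-parameter (codim-1) curves come in two flavours.  Bifurcations *of
the uniform state* are computed through the spatial-mode reduction: at a
uniform state the Jacobian block-diagonalizes over the graph-Laplacian
eigenvalues mu into 2x2 blocks A(mu) = J_cell - mu*diag(q*k_ADP, k_ADP),
so a Hopf of mode mu is tr A = 0 (with det A > 0, frequency
omega = sqrt(det A)) and a symmetry-breaking branch point is det A = 0.
These scalar conditions are continued directly; a Hopf curve terminates
where det A -> 0 (Bogdanov--Takens, omega -> 0), and intersections of two
mode curves mark double-Hopf points.  Bifurcations of *non-uniform*
states have no such reduction and are continued sequentially: the state
is tracked in the second parameter while the bifurcation is re-localized
in the first by bisection on the eigenvalue test function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import (
    ArrayTopology,
    CellArrayState,
    KineticParams,
    apply_permutation,
    automorphisms,
    jac_z,
    mode_matrix,
    rhs_param_deriv,
    rhs_z,
    single_cell_jacobian,
    uniform_steady_state,
)
from .steady_states import (
    NewtonError,
    StationaryState,
    enumerate_states,
    newton_solve,
)

__all__ = [
    "Branch",
    "BranchPointRecord",
    "BifurcationPoint",
    "RegionLabel",
    "trace_branch",
    "detect_bifurcations",
    "switch_branch",
    "trace_codim1_curve",
    "uniform_mode_curve",
    "secondary_hopf_curve",
    "region_map",
    "solution_diagram",
]

FREE_PARAMETERS = ("sigma_M", "sigma_inh", "k_ADP", "q")
RESIDUAL_TOL = 1e-10
STABILITY_TOL = 1e-9


@dataclass
class BranchPointRecord:
    """One converged point along a branch."""

    param: float
    z: np.ndarray
    eigenvalues: np.ndarray
    stable: bool
    tangent: np.ndarray          # (2N+1,) unit tangent in scaled coordinates
    n_unstable: int
    det_sign: float


@dataclass
class BifurcationPoint:
    """A localized codimension-1 bifurcation on a branch."""

    kind: str                    # hopf | fold | branch_point
    param: float
    z: np.ndarray
    free_parameter: str
    omega: float | None = None   # Hopf frequency (rad/s)
    test_residual: float = np.nan
    null_vector: np.ndarray | None = None


@dataclass
class Branch:
    """Ordered continuation output in one free parameter."""

    free_parameter: str
    points: list[BranchPointRecord]
    params_base: KineticParams
    topology: ArrayTopology
    bifurcations: list[BifurcationPoint] = field(default_factory=list)

    @property
    def param_values(self) -> np.ndarray:
        return np.array([pt.param for pt in self.points])

    def states(self) -> np.ndarray:
        return np.array([pt.z for pt in self.points])

    def stability_windows(self) -> list[tuple[float, float]]:
        """Closed parameter intervals over which the branch is stable."""
        if not self.points:
            return []
        windows = []
        start = None
        prev = self.points[0].param
        for pt in self.points:
            if pt.stable and start is None:
                start = pt.param
            elif not pt.stable and start is not None:
                windows.append((min(start, prev), max(start, prev)))
                start = None
            prev = pt.param
        if start is not None:
            windows.append((min(start, prev), max(start, prev)))
        return windows

    def to_frame(self):
        import pandas as pd

        N = self.topology.N
        rows = []
        for pt in self.points:
            row = {self.free_parameter: pt.param,
                   "max_re_eig_per_s": float(pt.eigenvalues.real.max()),
                   "stable": pt.stable}
            for i in range(N):
                row[f"x{i + 1}_dimensionless"] = pt.z[i]
                row[f"y{i + 1}_dimensionless"] = pt.z[N + i]
            rows.append(row)
        return pd.DataFrame(rows)


def _with_param(params: KineticParams, name: str, value: float) -> KineticParams:
    return params.replace(**{name: float(value)})


def _eig_info(z, params, topology):
    ev = np.linalg.eigvals(jac_z(z, params, topology))
    n_unst = int(np.sum(ev.real > STABILITY_TOL))
    sign, logdet = np.linalg.slogdet(jac_z(z, params, topology))
    return ev, n_unst, sign


class _Problem:
    """Scaled extended system for pseudo-arclength continuation."""

    def __init__(self, params, topology, free_parameter, prange, z_scale):
        self.params = params
        self.topology = topology
        self.name = free_parameter
        self.p_scale = max(prange[1] - prange[0], 1e-12)
        self.z_scale = z_scale

    def to_u(self, z, p):
        return np.concatenate([z / self.z_scale, [p / self.p_scale]])

    def from_u(self, u):
        return u[:-1] * self.z_scale, u[-1] * self.p_scale

    def residual(self, u):
        z, p = self.from_u(u)
        return rhs_z(z, _with_param(self.params, self.name, p), self.topology)

    def ext_jac(self, u):
        """d residual / d u (scaled), shape (2N, 2N+1)."""
        z, p = self.from_u(u)
        par = _with_param(self.params, self.name, p)
        Jz = jac_z(z, par, self.topology) * self.z_scale[None, :]
        Jp = rhs_param_deriv(z, par, self.topology, self.name) * self.p_scale
        return np.column_stack([Jz, Jp])

    def tangent(self, u, prev_tangent):
        A = np.vstack([self.ext_jac(u), prev_tangent])
        rhs_vec = np.zeros(len(u))
        rhs_vec[-1] = 1.0
        t = np.linalg.solve(A, rhs_vec)
        return t / np.linalg.norm(t)

    def correct(self, u_pred, tangent, tol=RESIDUAL_TOL, max_iter=12):
        u = u_pred.copy()
        for it in range(max_iter):
            r = self.residual(u)
            c = tangent @ (u - u_pred)
            if np.abs(r).max() < tol and abs(c) < 1e-12:
                return u, it
            A = np.vstack([self.ext_jac(u), tangent])
            du = np.linalg.solve(A, np.concatenate([r, [c]]))
            u = u - du
            if not np.all(np.isfinite(u)):
                raise NewtonError("corrector diverged", np.inf)
        raise NewtonError("corrector did not converge", float(np.abs(r).max()))


def trace_branch(start: StationaryState | CellArrayState,
                 params: KineticParams, topology: ArrayTopology,
                 free_parameter: str, prange: tuple[float, float],
                 step0: float = 1e-2, max_step: float = 0.05,
                 min_step: float = 1e-6, max_points: int = 2000,
                 direction: int = +1) -> Branch:
    """Pseudo-arclength continuation of a stationary state.

    ``params`` supplies the starting value of the free parameter; the
    branch is traced in ``direction`` until it leaves ``prange`` or
    ``max_points`` is reached.  Steps are in scaled arclength (the
    parameter scaled by the window width, states by their magnitude).
    """
    if free_parameter not in FREE_PARAMETERS:
        raise ValueError(f"free parameter must be one of {FREE_PARAMETERS}")
    z0 = start.z if hasattr(start, "z") else np.asarray(start)
    p0 = getattr(params, free_parameter)
    if not (prange[0] <= p0 <= prange[1]):
        raise ValueError("starting parameter value outside prange")
    z_scale = np.maximum(np.abs(z0), 1.0)
    prob = _Problem(params, topology, free_parameter, prange, z_scale)

    # converge the seed at fixed parameter
    st = newton_solve(CellArrayState.from_z(z0), params, topology)
    u = prob.to_u(st.z, p0)
    e_p = np.zeros(len(u))
    e_p[-1] = direction
    t = prob.tangent(u, e_p)
    if t[-1] * direction < 0:
        t = -t

    branch = Branch(free_parameter, [], params, topology)

    def record(u, t):
        z, p = prob.from_u(u)
        ev, n_unst, dsign = _eig_info(z, _with_param(params, free_parameter, p), topology)
        branch.points.append(BranchPointRecord(
            param=float(p), z=z.copy(), eigenvalues=ev,
            stable=bool(ev.real.max() < -STABILITY_TOL),
            tangent=t.copy(), n_unstable=n_unst, det_sign=dsign))

    record(u, t)
    u_start = u.copy()
    h = step0
    while len(branch.points) < max_points:
        tried = False
        while True:
            u_pred = u + h * t
            try:
                u_new, n_it = prob.correct(u_pred, t)
                break
            except (NewtonError, np.linalg.LinAlgError):
                h *= 0.5
                tried = True
                if h < min_step:
                    return branch  # truncated; caller sees fewer points
        t_new = prob.tangent(u_new, t)
        if t_new @ t < 0:
            t_new = -t_new
        u, t = u_new, t_new
        record(u, t)
        p = branch.points[-1].param
        if not (prange[0] - 1e-12 <= p <= prange[1] + 1e-12):
            break
        if len(branch.points) > 10 and np.linalg.norm(u - u_start) < 2 * h:
            break  # branch closed into a loop
        if not tried and n_it <= 3:
            h = min(h * 1.4, max_step)
    return branch


# ---------------------------------------------------------------------------
# bifurcation detection along a branch

def _resolve_fraction(prob: _Problem, u_a, u_b, frac):
    """Corrected point at a fraction of the secant between two branch points."""
    t_ab = (u_b - u_a)
    t_ab = t_ab / np.linalg.norm(t_ab)
    u_pred = u_a + frac * (u_b - u_a)
    u, _ = prob.correct(u_pred, t_ab)
    return u


def _is_uniform_branch(branch: Branch, tol: float = 1e-8) -> bool:
    N = branch.topology.N
    return all(np.ptp(pt.z[:N]) + np.ptp(pt.z[N:]) < tol * max(np.abs(pt.z).max(), 1.0)
               for pt in branch.points)


def _uniform_z(params: KineticParams, N: int) -> np.ndarray:
    xs, ys = uniform_steady_state(params)
    return np.concatenate([np.full(N, xs), np.full(N, ys)])


def _detect_on_uniform_branch(branch: Branch, tol: float) -> list[BifurcationPoint]:
    """Per-mode analytic tests along a uniform branch.

    Over each Laplacian eigenvalue mu the Jacobian reduces to the 2x2
    block A(mu); a Hopf of mode mu is a root of tr A (with det A > 0) and
    a symmetry-breaking branch point of mode mu > 0 is a root of det A.
    Roots are sharpened by brentq directly in the parameter (the uniform
    state is available in closed form at any parameter value).
    """
    params, topology = branch.params_base, branch.topology
    name = branch.free_parameter
    N = topology.N
    mus, mode_vecs = np.linalg.eigh(topology.laplacian)
    found: list[BifurcationPoint] = []
    seen: list[tuple[str, float]] = []

    def test(kind, mu):
        def f(p):
            t = _uniform_mode_test(_with_param(params, name, p), mu, kind)
            return np.nan if t is None else t
        return f

    pvals = branch.param_values
    for idx, mu in enumerate(mus):
        mu = float(max(mu, 0.0))
        for kind in ("hopf", "branch_point"):
            if kind == "branch_point" and mu < 1e-9:
                continue  # uniform-mode det roots are folds of the uniform state
            f = test(kind, mu)
            vals = np.array([f(p) for p in pvals])
            for a, b, va, vb in zip(pvals, pvals[1:], vals, vals[1:]):
                if not (np.isfinite(va) and np.isfinite(vb)) or va * vb > 0:
                    continue
                r = brentq(f, min(a, b), max(a, b), xtol=tol)
                if any(k == kind and abs(r - p) < 10 * tol for k, p in seen):
                    continue
                seen.append((kind, r))
                par = _with_param(params, name, r)
                z = _uniform_z(par, N)
                omega = None
                null = None
                if kind == "hopf":
                    det = _uniform_mode_test(par, mu, "branch_point")
                    if det is None or det <= 0:
                        continue  # real pair: not a Hopf
                    omega = float(np.sqrt(det))
                else:
                    A = mode_matrix(mu, par, z[0], z[N])
                    w, v = np.linalg.eig(A)
                    k2 = int(np.argmin(np.abs(w)))
                    cell_null = np.real(v[:, k2])
                    spatial = mode_vecs[:, idx]
                    null = np.concatenate([cell_null[0] * spatial, cell_null[1] * spatial])
                    null /= np.linalg.norm(null)
                found.append(BifurcationPoint(kind, float(r), z, name, omega=omega,
                                              test_residual=abs(f(r)),
                                              null_vector=null))
    found.sort(key=lambda bp: bp.param)
    return found


def _match_eigs(ev_a: np.ndarray, ev_b: np.ndarray) -> list[tuple[int, int]]:
    """Pair eigenvalues of consecutive points by nearest distance."""
    from scipy.optimize import linear_sum_assignment

    cost = np.abs(ev_a[:, None] - ev_b[None, :])
    ii, jj = linear_sum_assignment(cost)
    return list(zip(ii, jj))


def detect_bifurcations(branch: Branch, tol: float = 1e-8) -> list[BifurcationPoint]:
    """Locate folds, Hopf points and branch points along a branch.

    Uniform branches use the exact spatial-mode reduction.  On general
    branches, eigenvalues of consecutive points are paired by nearest
    matching; a matched real eigenvalue crossing zero marks a fold or
    branch point (told apart by whether the branch tangent is
    parameter-critical, threshold 1e-3 on the scaled tangent), and a
    complex pair crossing marks a Hopf.  Each crossing is sharpened by
    bisection with the corrector re-solving the state between the
    bracketing points.
    """
    if len(branch.points) < 2:
        return []
    if _is_uniform_branch(branch):
        branch.bifurcations = _detect_on_uniform_branch(branch, tol)
        return branch.bifurcations

    params, topology = branch.params_base, branch.topology
    name = branch.free_parameter
    pvals = branch.param_values
    prange = (pvals.min() - 1e-9, pvals.max() + 1e-9)
    z_scale = np.maximum(np.abs(branch.points[0].z), 1.0)
    prob = _Problem(params, topology, name, prange, z_scale)
    found: list[BifurcationPoint] = []

    def eigs_at(u):
        z, p = prob.from_u(u)
        return np.linalg.eigvals(jac_z(z, _with_param(params, name, p), topology))

    for a, b in zip(branch.points, branch.points[1:]):
        pairs = _match_eigs(a.eigenvalues, b.eigenvalues)
        crossings = []
        for i, j in pairs:
            ra, rb = a.eigenvalues[i].real, b.eigenvalues[j].real
            if ra * rb >= 0 or max(abs(ra), abs(rb)) < STABILITY_TOL:
                continue
            is_complex = abs(a.eigenvalues[i].imag) > 1e-9 or abs(b.eigenvalues[j].imag) > 1e-9
            if is_complex and a.eigenvalues[i].imag < 0:
                continue  # count each conjugate pair once
            crossings.append((i, j, is_complex))
        for i, j, is_complex in crossings:
            u_a = prob.to_u(a.z, a.param)
            u_b = prob.to_u(b.z, b.param)
            target_a = a.eigenvalues[i]
            lo, hi, f_lo = 0.0, 1.0, target_a.real
            u_mid, ev_mid = u_a, a.eigenvalues
            track = target_a
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                try:
                    u_mid = _resolve_fraction(prob, u_a, u_b, mid)
                except (NewtonError, np.linalg.LinAlgError):
                    break
                ev_mid = eigs_at(u_mid)
                k = int(np.argmin(np.abs(ev_mid - track)))
                f_mid = ev_mid[k].real
                track = ev_mid[k]
                if f_mid * f_lo > 0:
                    lo, f_lo = mid, f_mid
                else:
                    hi = mid
                if (hi - lo) * abs(b.param - a.param) < tol:
                    break
            z, p = prob.from_u(u_mid)
            if is_complex:
                omega = float(abs(track.imag))
                found.append(BifurcationPoint("hopf", float(p), z.copy(), name,
                                              omega=omega,
                                              test_residual=abs(track.real)))
            else:
                par = _with_param(params, name, p)
                J = jac_z(z, par, topology)
                w, v = np.linalg.eig(J)
                k = int(np.argmin(np.abs(w)))
                null = np.real(v[:, k])
                null /= np.linalg.norm(null)
                t_here = prob.tangent(prob.to_u(z, p), a.tangent)
                kind = "fold" if abs(t_here[-1]) < 1e-3 else "branch_point"
                found.append(BifurcationPoint(kind, float(p), z.copy(), name,
                                              test_residual=float(abs(w[k])),
                                              null_vector=null))
    # merge duplicates (the same crossing seen from both eigenvalues of a pair)
    uniq: list[BifurcationPoint] = []
    for bp in sorted(found, key=lambda b: b.param):
        if any(u.kind == bp.kind and abs(u.param - bp.param) < 1e-6 * max(abs(bp.param), 1.0)
               for u in uniq):
            continue
        uniq.append(bp)
    branch.bifurcations = uniq
    return uniq


def switch_branch(bp: BifurcationPoint, params: KineticParams,
                  topology: ArrayTopology, offset: float = 1e-2,
                  dedup_tol: float = 1e-5) -> list[StationaryState]:
    """Seed and converge the branches emanating at a symmetry-breaking point.

    Perturbs the state along the Jacobian null vector on both sides (and
    nudges the parameter slightly off the singular value) and corrects at
    fixed parameter; returns converged states that left the original branch.
    """
    if bp.kind != "branch_point":
        raise ValueError("branch switching requires a branch point")
    if bp.null_vector is None:
        raise ValueError("branch point carries no null vector")
    scale = max(np.abs(bp.z).max(), 1.0)
    out: list[StationaryState] = []
    for dp in (0.0, 1e-4, -1e-4):
        par = _with_param(params, bp.free_parameter, bp.param * (1 + dp) if bp.param else dp)
        for sgn in (+1, -1):
            z0 = bp.z + sgn * offset * scale * bp.null_vector
            try:
                st = newton_solve(CellArrayState.from_z(np.maximum(z0, 0.0)), par, topology)
            except NewtonError:
                continue
            if np.abs(st.z - bp.z).max() < dedup_tol * scale:
                continue  # fell back onto the original branch
            if not any(np.abs(st.z - o.z).max() < dedup_tol * scale
                       and getattr(o.params, bp.free_parameter) == getattr(par, bp.free_parameter)
                       for o in out):
                out.append(st)
    return out


# ---------------------------------------------------------------------------
# two-parameter curves

@dataclass
class Codim1Curve:
    """Polyline of a codimension-1 bifurcation in a 2-parameter plane."""

    kind: str                       # hopf | branch_point | fold
    parameter_pair: tuple[str, str]
    points: np.ndarray              # (n, 2): columns follow parameter_pair
    omegas: np.ndarray | None = None
    mode: float | None = None       # Laplacian eigenvalue, for uniform-state curves
    codim2: list[tuple[str, float, float]] = field(default_factory=list)


def _uniform_mode_test(params: KineticParams, mu: float, kind: str) -> float | None:
    """Scalar test function of the mode-reduced 2x2 block at the uniform state."""
    try:
        xs, ys = uniform_steady_state(params)
    except ValueError:
        return None
    A = mode_matrix(mu, params, xs, ys)
    if kind == "hopf":
        return A[0, 0] + A[1, 1]
    return A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]


def uniform_mode_curve(params: KineticParams, topology: ArrayTopology,
                       kind: str, parameter_pair: tuple[str, str],
                       ranges: tuple[tuple[float, float], tuple[float, float]],
                       mu: float, n_grid: int = 80) -> Codim1Curve:
    """Codim-1 curve of the uniform state for one spatial mode.

    Scans the *second* parameter of the pair on a grid and root-finds the
    first on the mode test function (tr A for Hopf, det A for symmetry
    breaking).  Hopf roots with det A <= 0 are discarded (beyond the
    Bogdanov--Takens point the pair is real); omega = sqrt(det A).
    """
    p1, p2 = parameter_pair
    (lo1, hi1), (lo2, hi2) = ranges
    pts, omegas = [], []
    codim2 = []
    prev_det = None
    for v2 in np.linspace(lo2, hi2, n_grid):
        base = _with_param(params, p2, v2)

        def test(v1):
            t = _uniform_mode_test(_with_param(base, p1, v1), mu, kind)
            return np.nan if t is None else t

        grid1 = np.linspace(lo1, hi1, n_grid)
        vals = np.array([test(v) for v in grid1])
        for a, b, va, vb in zip(grid1, grid1[1:], vals, vals[1:]):
            if not (np.isfinite(va) and np.isfinite(vb)) or va * vb > 0:
                continue
            r = brentq(test, a, b, xtol=1e-10)
            pr = _with_param(base, p1, r)
            det = _uniform_mode_test(pr, mu, "branch_point")
            if kind == "hopf":
                if det is None or det <= 0:
                    if prev_det is not None and prev_det > 0:
                        codim2.append(("bogdanov_takens", r, v2))
                    prev_det = det
                    continue
                omegas.append(np.sqrt(det))
                prev_det = det
            pts.append((r, v2))
    curve = Codim1Curve(kind, parameter_pair, np.array(pts) if pts else np.empty((0, 2)),
                        np.array(omegas) if kind == "hopf" else None, mu, codim2)
    return curve


def double_hopf_points(curve_a: Codim1Curve, curve_b: Codim1Curve,
                       tol: float | None = None) -> list[tuple[float, float]]:
    """Approximate intersections of two Hopf curves (double-Hopf candidates)."""
    if not len(curve_a.points) or not len(curve_b.points):
        return []
    if tol is None:
        tol = 0.05 * max(np.ptp(curve_a.points[:, 0]) + 1e-12,
                         np.ptp(curve_a.points[:, 1]) + 1e-12)
    out = []
    for pa in curve_a.points:
        d = np.abs(curve_b.points - pa).max(axis=1)
        if d.min() < tol:
            out.append(tuple(pa))
    return out


def secondary_hopf_curve(params: KineticParams, topology: ArrayTopology,
                         seed_state: StationaryState,
                         parameter_pair: tuple[str, str],
                         p1_range: tuple[float, float],
                         p2_values: np.ndarray,
                         p1_step: float = 2.0,
                         bisect_tol: float = 1e-3) -> Codim1Curve:
    """Hopf curve of a non-uniform branch by sequential continuation.

    For each value of the second parameter, the seed state is tracked in
    the first parameter (warm-started Newton walk) from the stable side
    until stability is lost, and the crossing is sharpened by bisection
    on the leading eigenvalue real part.  Rows where the state ceases to
    exist or never loses stability are skipped.
    """
    p1, p2 = parameter_pair
    pts = []
    omegas = []
    z_seed = seed_state.z.copy()
    p1_start = getattr(seed_state.params, p1)
    for v2 in p2_values:
        base = _with_param(params, p2, float(v2))
        z = z_seed.copy()
        # walk down in p1 from the seed value, tracking the state
        last_stable = None
        bracket = None
        for v1 in np.arange(p1_start, p1_range[0] - 1e-9, -abs(p1_step)):
            par = _with_param(base, p1, float(v1))
            try:
                st = newton_solve(CellArrayState.from_z(z), par, topology)
            except (NewtonError, ValueError):
                break
            z = st.z
            if st.stable:
                last_stable = (v1, st.z.copy())
            elif last_stable is not None:
                bracket = (v1, last_stable[0])
                break
        if bracket is None:
            continue
        lo, hi = bracket
        z_hi = last_stable[1]
        omega = None
        while hi - lo > bisect_tol:
            mid = 0.5 * (lo + hi)
            par = _with_param(base, p1, mid)
            try:
                st = newton_solve(CellArrayState.from_z(z_hi), par, topology)
            except (NewtonError, ValueError):
                break
            if st.stable:
                hi, z_hi = mid, st.z
            else:
                lo = mid
            cplx = st.eigenvalues[np.abs(st.eigenvalues.imag) > 1e-9]
            if len(cplx):
                omega = float(abs(cplx.imag[np.argmax(cplx.real)]))
        pts.append((0.5 * (lo + hi), float(v2)))
        omegas.append(omega if omega is not None else np.nan)
        z_seed = z_hi  # warm start for the next column
        p1_start = min(hi + 10 * abs(p1_step), p1_range[1])
    return Codim1Curve("hopf", parameter_pair,
                       np.array(pts) if pts else np.empty((0, 2)),
                       np.array(omegas) if omegas else None)


def trace_codim1_curve(bp: BifurcationPoint, params: KineticParams,
                       topology: ArrayTopology,
                       parameter_pair: tuple[str, str],
                       ranges: tuple[tuple[float, float], tuple[float, float]],
                       n_grid: int = 60) -> list[Codim1Curve]:
    """Continue a detected codim-1 point in a second parameter.

    Dispatches on the nature of the starting point: bifurcations of the
    uniform state use the exact spatial-mode reduction (one curve per
    non-uniform Laplacian mode, plus the uniform mode for Hopf);
    non-uniform Hopf points fall back to sequential continuation.
    """
    N = topology.N
    z = bp.z
    is_uniform = (np.ptp(z[:N]) + np.ptp(z[N:])) < 1e-6 * max(np.abs(z).max(), 1.0)
    if is_uniform:
        mus = np.linalg.eigvalsh(topology.laplacian)
        kind = "hopf" if bp.kind == "hopf" else "branch_point"
        curves = []
        for mu in np.unique(np.round(mus, 9)):
            if kind == "branch_point" and mu < 1e-9:
                continue
            c = uniform_mode_curve(params, topology, kind, parameter_pair,
                                   ranges, float(mu), n_grid)
            if len(c.points):
                curves.append(c)
        return curves
    if bp.kind != "hopf":
        raise NotImplementedError("non-uniform codim-1 continuation is "
                                  "implemented for Hopf points only")
    seed = newton_solve(CellArrayState.from_z(z),
                        _with_param(params, bp.free_parameter, bp.param), topology)
    p1, p2 = parameter_pair
    p2_values = np.linspace(*ranges[1], n_grid)
    return [secondary_hopf_curve(params, topology, seed, parameter_pair,
                                 ranges[0], p2_values)]


# ---------------------------------------------------------------------------
# region maps and solution diagrams

@dataclass
class RegionLabel:
    """(m, n) state counts at one node of a 2-parameter grid."""

    p1: float
    p2: float
    m: int                      # total stationary states
    n: int                      # stable stationary states
    n_stable_nonuniform: int


def region_map(parameter_pair: tuple[str, str],
               grid: tuple[np.ndarray, np.ndarray],
               params: KineticParams, topology: ArrayTopology,
               n_starts: int = 512, seed: int = 0) -> list[RegionLabel]:
    """Enumerate stationary states on a parameter grid and label (m, n).

    Neighbouring nodes warm-start each other, which stabilizes the counts
    of the multistart enumeration across the grid.
    """
    p1_name, p2_name = parameter_pair
    g1, g2 = grid
    labels: list[RegionLabel] = []
    warm: np.ndarray | None = None
    for v2 in g2:
        for v1 in g1:
            par = _with_param(_with_param(params, p1_name, float(v1)), p2_name, float(v2))
            try:
                states = enumerate_states(par, topology, n_starts=n_starts,
                                          seed=seed, extra_guesses=warm)
            except ValueError:
                labels.append(RegionLabel(float(v1), float(v2), 0, 0, 0))
                warm = None
                continue
            warm = np.array([s.z for s in states]) if states else None
            labels.append(RegionLabel(
                float(v1), float(v2), len(states),
                sum(1 for s in states if s.stable),
                sum(1 for s in states if s.stable and s.symmetry != "uniform")))
    return labels


def solution_diagram(params: KineticParams, topology: ArrayTopology,
                     free_parameter: str, prange: tuple[float, float],
                     max_depth: int = 2, max_step: float = 0.02,
                     max_points: int = 1200) -> list[Branch]:
    """One-parameter diagram: uniform branch plus recursive branch switching.

    Traces the uniform branch across ``prange``, switches at every
    symmetry-breaking point, and repeats on the emanating (symmetric, then
    asymmetric) branches up to ``max_depth`` switching generations.
    Branches are deduplicated by comparing states at matched parameter
    values; the full diagram is closed under the automorphism group only
    up to that deduplication (orbit images are not re-traced).
    """
    xs, ys = uniform_steady_state(
        _with_param(params, free_parameter, 0.5 * (prange[0] + prange[1])))
    N = topology.N
    z0 = np.concatenate([np.full(N, xs), np.full(N, ys)])
    p_mid = 0.5 * (prange[0] + prange[1])
    par0 = _with_param(params, free_parameter, p_mid)
    branches: list[Branch] = []
    queue: list[tuple[StationaryState | CellArrayState, KineticParams, int]] = []
    st0 = newton_solve(CellArrayState.from_z(z0), par0, topology)
    queue.append((st0, par0, 0))
    seen: list[tuple[float, np.ndarray]] = []

    def known(p, z):
        scale = max(np.abs(z).max(), 1.0)
        return any(abs(p - ps) < 1e-6 * max(abs(p), 1.0)
                   and np.abs(z - zs).max() < 1e-4 * scale for ps, zs in seen)

    while queue:
        st, par, depth = queue.pop(0)
        p_here = getattr(par, free_parameter)
        if known(p_here, st.z):
            continue
        halves = []
        for direction in (+1, -1):
            b = trace_branch(st, par, topology, free_parameter, prange,
                             max_step=max_step, direction=direction,
                             max_points=max_points)
            halves.append(b)
        pts = halves[1].points[::-1] + halves[0].points[1:]
        b = Branch(free_parameter, pts, par, topology)
        for pt in pts[:: max(len(pts) // 40, 1)]:
            seen.append((pt.param, pt.z))
        detect_bifurcations(b)
        branches.append(b)
        if depth < max_depth:
            for bp in b.bifurcations:
                if bp.kind != "branch_point":
                    continue
                par_bp = _with_param(par, free_parameter, bp.param)
                for new_st in switch_branch(bp, par_bp, topology):
                    queue.append((new_st, new_st.params, depth + 1))
    return branches
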
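"""Stationary states of the array: root finding, enumeration, classification.

A *discrete Turing pattern* is a stable non-uniform stationary state.
States are labelled by stability (eigenvalues of the analytic Jacobian),
by symmetry class under the topology's automorphism group (uniform /
symmetric non-uniform / asymmetric non-uniform), and by their pattern
code (per-cell ADP binarized against the uniform level y*).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .dynamics import pattern_code
from .model import (
    ArrayTopology,
    CellArrayState,
    KineticParams,
    apply_permutation,
    automorphisms,
    jac_z,
    rhs_z,
    uniform_steady_state,
)

__all__ = [
    "StationaryState",
    "newton_solve",
    "enumerate_states",
    "assess_stability",
    "symmetry_class",
    "states_table",
]

RESIDUAL_TOL = 1e-10
STABILITY_TOL = 1e-9
DEDUP_TOL = 1e-6


@dataclass
class StationaryState:
    """A converged stationary state with stability and symmetry labels."""

    x: np.ndarray
    y: np.ndarray
    params: KineticParams
    topology: ArrayTopology
    eigenvalues: np.ndarray | None = None
    stable: bool | None = None
    symmetry: str | None = None
    code: str | None = None
    stabilizer_order: int | None = None
    orbit_size: int | None = None
    residual: float = np.nan

    @property
    def z(self) -> np.ndarray:
        return np.concatenate([self.x, self.y])

    @property
    def N(self) -> int:
        return self.x.size

    @property
    def max_real_eig(self) -> float:
        return float(self.eigenvalues.real.max())

    def as_state(self) -> CellArrayState:
        return CellArrayState(x=self.x.copy(), y=self.y.copy())


class NewtonError(RuntimeError):
    """Damped Newton failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def _finish(z: np.ndarray, params: KineticParams, topology: ArrayTopology,
            auts=None) -> StationaryState:
    """Wrap a converged root with eigenvalues, stability and symmetry labels."""
    N = topology.N
    st = StationaryState(
        x=z[:N].copy(), y=z[N:].copy(), params=params, topology=topology,
        residual=float(np.abs(rhs_z(z, params, topology)).max()))
    assess_stability(st)
    _, y_star = uniform_steady_state(params)
    st.code = pattern_code(st.y, y_star)
    if auts is None:
        auts = automorphisms(topology)
    symmetry_class(st, auts)
    return st


def newton_solve(guess: CellArrayState, params: KineticParams,
                 topology: ArrayTopology, max_iter: int = 50,
                 tol: float = RESIDUAL_TOL) -> StationaryState:
    """Damped Newton iteration on rhs = 0 from one starting point.

    Raises :class:`NewtonError` on non-convergence; roots with negative
    concentrations are rejected (they are not physically admissible).
    """
    z = guess.z.astype(float)
    if not np.all(np.isfinite(z)):
        raise ValueError("guess must be finite")
    res = np.abs(rhs_z(z, params, topology)).max()
    for _ in range(max_iter):
        if res < tol:
            break
        r = rhs_z(z, params, topology)
        J = jac_z(z, params, topology)
        try:
            step = np.linalg.solve(J, r)
        except np.linalg.LinAlgError as exc:
            raise NewtonError(f"singular Jacobian during Newton: {exc}", res) from exc
        lam = 1.0
        for _damp in range(30):
            z_new = z - lam * step
            res_new = np.abs(rhs_z(z_new, params, topology)).max()
            if res_new < res:
                break
            lam *= 0.5
        else:
            raise NewtonError(f"Newton line search stalled at residual {res:.3g}", res)
        z, res = z_new, res_new
    else:
        raise NewtonError(f"Newton did not converge in {max_iter} iterations "
                          f"(residual {res:.3g})", res)
    if z.min() < -1e-9:
        raise NewtonError(f"root has negative concentration ({z.min():.3g})", res)
    return _finish(np.maximum(z, 0.0), params, topology)


def _newton_batch(Z: np.ndarray, params: KineticParams, topology: ArrayTopology,
                  max_iter: int = 60, tol: float = RESIDUAL_TOL) -> np.ndarray:
    """Plain vectorized Newton from many starts; returns converged roots.

    Per-sample damping is replaced by step clipping; non-converged or
    negative samples are simply dropped (the multistart supplies volume).
    """
    Z = np.array(Z, dtype=float)
    step_cap = 0.5 * (Z.max(axis=0) - Z.min(axis=0) + 1.0).max()
    alive = np.ones(len(Z), dtype=bool)
    done = np.zeros(len(Z), dtype=bool)
    for _ in range(max_iter):
        act = alive & ~done
        if not act.any():
            break
        R = rhs_z(Z[act], params, topology)
        J = jac_z(Z[act], params, topology)
        try:
            steps = np.linalg.solve(J, R[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # kill exactly-singular samples one by one
            ok = np.abs(np.linalg.det(J)) > 1e-300
            idx = np.where(act)[0]
            alive[idx[~ok]] = False
            continue
        bad = ~np.isfinite(steps).all(axis=1)
        norms = np.linalg.norm(steps, axis=1)
        scale = np.minimum(1.0, step_cap / np.maximum(norms, 1e-300))
        Znew = Z[act] - steps * scale[:, None]
        idx = np.where(act)[0]
        alive[idx[bad]] = False
        Z[act] = Znew
        Rn = np.abs(rhs_z(Z[act], params, topology)).max(axis=1)
        done_now = Rn < tol
        diverged = ~np.isfinite(Rn) | (np.abs(Z[act]).max(axis=1) > 1e6)
        done[idx[done_now]] = True
        alive[idx[diverged]] = False
    good = done & alive & (Z.min(axis=1) > -1e-9)
    return np.maximum(Z[good], 0.0)


def _dedup(roots: np.ndarray, scale: np.ndarray, tol: float = DEDUP_TOL) -> np.ndarray:
    """Merge roots equal in the scaled max-norm within tol."""
    out: list[np.ndarray] = []
    for z in roots:
        if not any(np.max(np.abs(z - w) / scale) < tol for w in out):
            out.append(z)
    return np.array(out) if out else roots[:0]


def enumerate_states(params: KineticParams, topology: ArrayTopology,
                     box: tuple[float, float] | None = None,
                     n_starts: int = 512, seed: int = 0,
                     extra_guesses: np.ndarray | None = None) -> list[StationaryState]:
    """Multistart Newton enumeration of stationary states.

    Starts are a Sobol low-discrepancy sample of the per-cell box
    (default [0, 5 x*] x [0, 5 y*]; the oscillation maxima stay below
    about 2.6 y*, so the default box covers the observed ranges), plus
    the uniform state, plus optional warm-start guesses.  The result is
    closed under the topology's automorphism group and deduplicated in
    the scaled max-norm.  Enumeration is heuristic: it may miss states,
    and counts should stabilize as ``n_starts`` grows.
    """
    N = topology.N
    x_star, y_star = uniform_steady_state(params)
    if box is None:
        box = (5.0 * x_star, 5.0 * y_star)
    xmax, ymax = box
    sampler = qmc.Sobol(2 * N, scramble=True, rng=np.random.default_rng(seed))
    starts = sampler.random_base2(max(int(np.ceil(np.log2(n_starts))), 1))
    starts[:, :N] *= xmax
    starts[:, N:] *= ymax
    uniform = np.concatenate([np.full(N, x_star), np.full(N, y_star)])
    pool = [starts, uniform[None, :]]
    if extra_guesses is not None and len(extra_guesses):
        pool.append(np.asarray(extra_guesses, dtype=float))
    roots = _newton_batch(np.vstack(pool), params, topology)
    if not len(roots):
        return []
    auts = automorphisms(topology)
    images = np.vstack([apply_permutation(roots, perm) for perm in auts])
    scale = np.concatenate([np.full(N, max(x_star, 1.0)), np.full(N, max(y_star, 1.0))])
    uniq = _dedup(images, scale)
    states = [_finish(z, params, topology, auts) for z in uniq]
    _assign_orbits(states, auts, scale)
    order = {"uniform": 0, "symmetric_nonuniform": 1, "asymmetric_nonuniform": 2}
    states.sort(key=lambda s: (order[s.symmetry], -int(s.stable), s.code))
    return states


def _assign_orbits(states: list[StationaryState], auts, scale) -> None:
    """Group states into automorphism orbits; store orbit ids as orbit_size."""
    zs = [s.z for s in states]
    orbit_of = [-1] * len(states)
    next_id = 0
    for i, z in enumerate(zs):
        if orbit_of[i] >= 0:
            continue
        orbit_of[i] = next_id
        for perm in auts:
            pz = apply_permutation(z, perm)
            for j, w in enumerate(zs):
                if orbit_of[j] < 0 and np.max(np.abs(pz - w) / scale) < DEDUP_TOL:
                    orbit_of[j] = next_id
        next_id += 1
    for i, s in enumerate(states):
        s.orbit_id = orbit_of[i]


def assess_stability(state: StationaryState) -> StationaryState:
    """Full eigensolve of the analytic Jacobian; stable iff max Re < -1e-9."""
    J = jac_z(state.z, state.params, state.topology)
    ev = np.linalg.eigvals(J)
    state.eigenvalues = ev[np.argsort(-ev.real)]
    state.stable = bool(ev.real.max() < -STABILITY_TOL)
    return state


def symmetry_class(state: StationaryState, auts=None,
                   tol: float = 1e-6) -> str:
    """Classify a state by its stabilizer in the automorphism group.

    uniform: all cells equal; symmetric_nonuniform: fixed by some
    non-identity automorphism; asymmetric_nonuniform: trivial stabilizer.
    Orbit size = |G| / |stabilizer|.
    """
    if auts is None:
        auts = automorphisms(state.topology)
    scale = max(np.abs(state.z).max(), 1.0)
    z = state.z
    if max(np.ptp(state.x), np.ptp(state.y)) < tol * scale:
        state.symmetry = "uniform"
        state.stabilizer_order = len(auts)
        state.orbit_size = 1
        return state.symmetry
    stab = sum(1 for perm in auts
               if np.max(np.abs(apply_permutation(z, perm) - z)) < tol * scale)
    state.stabilizer_order = stab
    state.orbit_size = len(auts) // stab
    state.symmetry = "symmetric_nonuniform" if stab > 1 else "asymmetric_nonuniform"
    return state.symmetry


def states_table(states: list[StationaryState]):
    """One row per state: cell values, leading eigenvalue, labels (for CSV)."""
    import pandas as pd

    rows = []
    for s in states:
        row = {f"x{i + 1}_dimensionless": s.x[i] for i in range(s.N)}
        row.update({f"y{i + 1}_dimensionless": s.y[i] for i in range(s.N)})
        row.update({
            "max_re_eig_per_s": s.max_real_eig,
            "stable": s.stable,
            "symmetry": s.symmetry,
            "pattern_code": s.code,
            "orbit_id": getattr(s, "orbit_id", -1),
        })
        rows.append(row)
    return pd.DataFrame(rows)
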
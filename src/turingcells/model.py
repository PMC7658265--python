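"""Coupled-cell glycolytic core model.

An array of N continuous stirred tank reactors, each running the
Goldbeter--Moran skeleton model of glycolysis (ATP = inhibitor ``x``,
ADP = activator ``y``), mass-coupled through a symmetric structural
matrix ``delta``.  Per cell::

    dx_i/dt = f_x(x_i, y_i) + q*k_ADP * sum_j delta_ij (x_j - x_i) + p_i(t)
    dy_i/dt = f_y(x_i, y_i) +   k_ADP * sum_j delta_ij (y_j - y_i)

with the single-cell kinetics

    f_x = nu + sigma_inh * y^n/(M^n + y^n)
             - sigma_M * x(1+x)(1+y)^2 / (L + (1+x)^2 (1+y)^2)
    f_y = phi*sigma_M * x(1+x)(1+y)^2 / (L + (1+x)^2 (1+y)^2)
             - k_s*y - phi*sigma_inh * y^n/(M^n + y^n)

The algebraic identity ``phi*f_x + f_y = phi*nu - k_s*y`` pins the uniform
stationary ADP level at ``y* = phi*nu/k_s`` independently of sigma_M and
sigma_inh; the uniform ATP level x* is the unique root of f_x(x, y*) = 0.

Cells are numbered 1..N in all user-facing I/O; internal arrays are 0-based.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KineticParams",
    "ArrayTopology",
    "CellArrayState",
    "build_topology",
    "automorphisms",
    "rhs",
    "jacobian",
    "uniform_steady_state",
    "single_cell_jacobian",
    "mode_matrix",
]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and coupling ratios of the coupled-cell model.

    Defaults are the standard Goldbeter--Moran setting (phi = 1,
    nu = 1.84 1/s, L = 5e6, n = 4, M = 10, k_s = 0.06 1/s) with the
    adjustable pair sigma_M, sigma_inh at the workhorse values used for
    the chemical-computing devices, and coupling q = 1, k_ADP = 0.1 1/s.
    """

    sigma_M: float = 100.0      # autocatalysis rate coefficient (1/s)
    sigma_inh: float = 35.0     # inhibition rate coefficient (1/s)
    nu: float = 1.84            # ATP uptake rate (1/s)
    M: float = 10.0             # Michaelis constant (dimensionless)
    n: int = 4                  # Hill coefficient
    L: float = 5.0e6            # allosteric constant (dimensionless)
    phi: float = 1.0            # ratio of ATP/ADP dissociation constants
    k_s: float = 0.06           # ADP removal rate coefficient (1/s)
    q: float = 1.0              # ATP/ADP transport-coefficient ratio
    k_ADP: float = 0.1          # ADP transport coefficient (1/s)

    def __post_init__(self) -> None:
        for name in ("sigma_M", "sigma_inh", "nu", "M", "L", "phi", "k_s"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not float(self.n).is_integer() or self.n < 1:
            raise ValueError(f"Hill coefficient n must be an integer >= 1, got {self.n!r}")
        for name in ("q", "k_ADP"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")

    def replace(self, **kw) -> "KineticParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ArrayTopology:
    """Cell count N plus the symmetric structural matrix {delta_ij}."""

    N: int
    delta: np.ndarray
    kind: str = "custom"

    def __post_init__(self) -> None:
        d = np.asarray(self.delta, dtype=float)
        if d.shape != (self.N, self.N):
            raise ValueError(f"delta must be {self.N}x{self.N}, got {d.shape}")
        if np.any(d < 0):
            raise ValueError("delta entries must be non-negative")
        if not np.allclose(d, d.T):
            raise ValueError("delta must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("delta must have zero diagonal")
        d.setflags(write=False)
        object.__setattr__(self, "delta", d)

    @property
    def laplacian(self) -> np.ndarray:
        """Graph Laplacian L = diag(deg) - delta (weighted)."""
        return np.diag(self.delta.sum(axis=1)) - self.delta

    @property
    def degrees(self) -> np.ndarray:
        return self.delta.sum(axis=1)

    def edges(self) -> list[tuple[int, int]]:
        """Edge list with 1-based cell indices, i < j."""
        ii, jj = np.nonzero(np.triu(self.delta))
        return [(int(i) + 1, int(j) + 1) for i, j in zip(ii, jj)]


@dataclass
class CellArrayState:
    """ATP/ADP concentration vectors of the array at one time point."""

    x: np.ndarray
    y: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D vectors of equal length")

    @property
    def N(self) -> int:
        return self.x.size

    @property
    def z(self) -> np.ndarray:
        """Stacked state vector [x_1..x_N, y_1..y_N]."""
        return np.concatenate([self.x, self.y])

    @classmethod
    def from_z(cls, z: np.ndarray, t: float = 0.0) -> "CellArrayState":
        z = np.asarray(z, dtype=float)
        N = z.size // 2
        return cls(x=z[:N].copy(), y=z[N:].copy(), t=t)


# ---------------------------------------------------------------------------
# topologies

def build_topology(kind: str, N: int) -> ArrayTopology:
    """Construct one of the built-in array topologies.

    linear   : chain 1-2-...-N
    cyclic   : chain plus the closing edge (1, N)
    t_shaped : N = 4 only; hub cell 2 bonded to leaves 1, 3, 4
    """
    if not isinstance(N, (int, np.integer)) or N < 1:
        raise ValueError(f"N must be an integer >= 1, got {N!r}")
    delta = np.zeros((N, N))
    if kind == "linear":
        for i in range(1, N):
            delta[i - 1, i] = delta[i, i - 1] = 1.0
    elif kind == "cyclic":
        if N < 3:
            raise ValueError("cyclic topology requires N >= 3")
        for i in range(1, N):
            delta[i - 1, i] = delta[i, i - 1] = 1.0
        delta[0, N - 1] = delta[N - 1, 0] = 1.0
    elif kind == "t_shaped":
        if N != 4:
            raise ValueError("t_shaped topology requires N = 4")
        for j in (0, 2, 3):  # hub is cell 2 (index 1)
            delta[1, j] = delta[j, 1] = 1.0
    else:
        raise ValueError(f"unknown topology kind {kind!r}")
    return ArrayTopology(N=N, delta=delta, kind=kind)


def automorphisms(topology: ArrayTopology) -> list[tuple[int, ...]]:
    """All cell permutations pi with delta[pi(i), pi(j)] = delta[i, j].

    Returned as tuples ``pi`` (0-based) with ``pi[i]`` the image of cell i.
    Brute-force search; array sizes of interest are tiny (N <= 8).
    """
    d = topology.delta
    out = []
    for perm in itertools.permutations(range(topology.N)):
        p = np.asarray(perm)
        if np.array_equal(d[np.ix_(p, p)], d):
            out.append(perm)
    return out


def apply_permutation(z: np.ndarray, perm: Sequence[int]) -> np.ndarray:
    """Permute a stacked state/derivative vector by a cell permutation.

    ``perm[i]`` is the image of cell i, i.e. (pi.z)[perm[i]] = z[i]
    for both the x and the y block.
    """
    z = np.asarray(z)
    N = z.shape[-1] // 2
    p = np.asarray(perm)
    out = np.empty_like(z)
    out[..., p] = z[..., :N]
    out[..., p + N] = z[..., N:]
    return out


# ---------------------------------------------------------------------------
# kinetics (vectorized over leading axes)

def _hill(y, p: KineticParams):
    yn = y ** p.n
    return yn / (p.M ** p.n + yn)


def _hill_dy(y, p: KineticParams):
    yn1 = y ** (p.n - 1)
    den = p.M ** p.n + y * yn1
    return p.n * p.M ** p.n * yn1 / (den * den)


def _sat(x, y, p: KineticParams):
    a = 1.0 + x
    b2 = (1.0 + y) ** 2
    return x * a * b2 / (p.L + a * a * b2)


def _sat_partials(x, y, p: KineticParams):
    a = 1.0 + x
    b = 1.0 + y
    b2 = b * b
    D = p.L + a * a * b2
    gx = b2 * ((1.0 + 2.0 * x) * D - 2.0 * x * a * a * b2) / (D * D)
    gy = 2.0 * x * a * b * p.L / (D * D)
    return gx, gy


def fx_cell(x, y, p: KineticParams):
    """Single-cell ATP kinetics f_x."""
    return p.nu + p.sigma_inh * _hill(y, p) - p.sigma_M * _sat(x, y, p)


def fy_cell(x, y, p: KineticParams):
    """Single-cell ADP kinetics f_y."""
    return p.phi * p.sigma_M * _sat(x, y, p) - p.k_s * y - p.phi * p.sigma_inh * _hill(y, p)


def rhs_z(z: np.ndarray, params: KineticParams, topology: ArrayTopology,
          pulse_values: np.ndarray | None = None) -> np.ndarray:
    """Time derivative for stacked states; batched over leading axes."""
    z = np.asarray(z, dtype=float)
    N = topology.N
    if z.shape[-1] != 2 * N:
        raise ValueError(f"state length {z.shape[-1]} does not match 2N = {2 * N}")
    x = z[..., :N]
    y = z[..., N:]
    lap = topology.laplacian
    dx = fx_cell(x, y, params) - params.q * params.k_ADP * (x @ lap.T)
    dy = fy_cell(x, y, params) - params.k_ADP * (y @ lap.T)
    if pulse_values is not None:
        dx = dx + np.asarray(pulse_values, dtype=float)
    return np.concatenate([dx, dy], axis=-1)


def jac_z(z: np.ndarray, params: KineticParams, topology: ArrayTopology) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs_z`; batched over leading axes."""
    z = np.asarray(z, dtype=float)
    N = topology.N
    x = z[..., :N]
    y = z[..., N:]
    gx, gy = _sat_partials(x, y, params)
    hy = _hill_dy(y, params)
    fxx = -params.sigma_M * gx
    fxy = params.sigma_inh * hy - params.sigma_M * gy
    fyx = params.phi * params.sigma_M * gx
    fyy = params.phi * params.sigma_M * gy - params.k_s - params.phi * params.sigma_inh * hy

    lap = topology.laplacian
    shape = z.shape[:-1] + (2 * N, 2 * N)
    J = np.zeros(shape)
    idx = np.arange(N)
    J[..., idx, idx] = fxx
    J[..., idx, idx + N] = fxy
    J[..., idx + N, idx] = fyx
    J[..., idx + N, idx + N] = fyy
    J[..., :N, :N] -= params.q * params.k_ADP * lap
    J[..., N:, N:] -= params.k_ADP * lap
    return J


def rhs(state: CellArrayState, params: KineticParams, topology: ArrayTopology,
        pulse_values: np.ndarray | None = None) -> np.ndarray:
    """Right-hand side of the coupled-cell equations at one state."""
    if state.N != topology.N:
        raise ValueError(f"state has {state.N} cells, topology has {topology.N}")
    if pulse_values is not None:
        pulse_values = np.asarray(pulse_values, dtype=float)
        if pulse_values.shape != (topology.N,):
            raise ValueError("pulse_values must have length N")
    if np.any(state.x < -1e-9) or np.any(state.y < -1e-9):
        raise ValueError("negative concentrations are not admissible")
    return rhs_z(state.z, params, topology, pulse_values)


def jacobian(state: CellArrayState, params: KineticParams,
             topology: ArrayTopology) -> np.ndarray:
    """Analytic 2N x 2N Jacobian of the coupled-cell right-hand side."""
    if state.N != topology.N:
        raise ValueError(f"state has {state.N} cells, topology has {topology.N}")
    return jac_z(state.z, params, topology)


def single_cell_jacobian(x: float, y: float, params: KineticParams) -> np.ndarray:
    """2x2 Jacobian of the uncoupled single-cell kinetics (f_x, f_y)."""
    gx, gy = _sat_partials(x, y, params)
    hy = _hill_dy(y, params)
    return np.array([
        [-params.sigma_M * gx, params.sigma_inh * hy - params.sigma_M * gy],
        [params.phi * params.sigma_M * gx,
         params.phi * params.sigma_M * gy - params.k_s - params.phi * params.sigma_inh * hy],
    ])


def mode_matrix(mu: float, params: KineticParams, x: float, y: float) -> np.ndarray:
    """Jacobian of one spatial mode at a uniform state.

    At a uniform state the full Jacobian block-diagonalizes over the
    eigenvalues ``mu`` of the graph Laplacian into 2x2 blocks
    ``J_cell - mu * diag(q*k_ADP, k_ADP)``; mu = 0 is the uniform mode.
    """
    J = single_cell_jacobian(x, y, params)
    J[0, 0] -= mu * params.q * params.k_ADP
    J[1, 1] -= mu * params.k_ADP
    return J


def rhs_param_deriv(z: np.ndarray, params: KineticParams, topology: ArrayTopology,
                    name: str) -> np.ndarray:
    """Analytic derivative of the right-hand side w.r.t. one free parameter.

    Supported free parameters: sigma_M, sigma_inh, k_ADP, q.
    """
    z = np.asarray(z, dtype=float)
    N = topology.N
    x = z[..., :N]
    y = z[..., N:]
    lap = topology.laplacian
    if name == "sigma_M":
        g = _sat(x, y, params)
        return np.concatenate([-g, params.phi * g], axis=-1)
    if name == "sigma_inh":
        h = _hill(y, params)
        return np.concatenate([h, -params.phi * h], axis=-1)
    if name == "k_ADP":
        return np.concatenate([-params.q * (x @ lap.T), -(y @ lap.T)], axis=-1)
    if name == "q":
        return np.concatenate([-params.k_ADP * (x @ lap.T), np.zeros_like(y)], axis=-1)
    raise ValueError(f"unsupported free parameter {name!r}")


def uniform_steady_state(params: KineticParams, xmax: float = 1e7) -> tuple[float, float]:
    """The uniform stationary state (x*, y*) of the array.

    y* = phi*nu/k_s in closed form; x* is the unique root of
    f_x(x, y*) = 0 (the saturation term is monotone in x, so the root is
    unique whenever it exists).
    """
    y_star = params.phi * params.nu / params.k_s
    target = (params.nu + params.sigma_inh * _hill(y_star, params)) / params.sigma_M

    def f(x):
        return fx_cell(x, y_star, params)

    if target >= 1.0:
        raise ValueError(
            "no uniform stationary state: nu + sigma_inh*h(y*) exceeds the "
            f"maximal autocatalytic rate sigma_M (saturation target {target:.3f} >= 1); "
            f"f_x(x, y*) -> {params.nu + params.sigma_inh * _hill(y_star, params) - params.sigma_M:.3g} "
            "as x -> inf"
        )
    hi = 1.0
    while f(hi) > 0:
        hi *= 4.0
        if hi > xmax:
            raise ValueError(
                f"root bracketing failed: f_x(0, y*) = {f(0.0):.3g}, "
                f"f_x({xmax:.3g}, y*) = {f(xmax):.3g}"
            )
    x_star = brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-15)
    return float(x_star), float(y_star)
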
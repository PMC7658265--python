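"""Canonical measurement protocols on the chemical-computing arrays.

Each function runs one complete, self-contained numerical experiment at
the standard study conditions (q = 1, sigma_M = 100 1/s, sigma_inh = 35
1/s, k_ADP = 0.1 1/s unless the protocol itself varies them) and returns
a scalar summary.  These are the protocols behind the headline numbers
of the package: oscillation periods, pattern robustness bounds, pattern
induction by pulse pairs, and the bifurcation-structure landmarks.
"""

from __future__ import annotations

import numpy as np

from .continuation import secondary_hopf_curve, uniform_mode_curve
from .dynamics import (
    PerturbationPulse,
    PerturbationSchedule,
    classify_regime,
    measure_period,
    pattern_code,
    perturbed_uniform_state,
    simulate,
)
from .model import ArrayTopology, CellArrayState, KineticParams, build_topology, uniform_steady_state
from .steady_states import enumerate_states

__all__ = [
    "single_cell_period",
    "two_cell_envelope_period",
    "install_tautology_pattern",
    "pattern_robustness_bound",
    "two_pulse_induction_max_delay",
    "secondary_hopf_min_sigma_M",
    "five_pattern_onset_sigma_M",
    "turing_region_max_sigma_inh",
]

GATE_PARAMS = KineticParams()  # sigma_M=100, sigma_inh=35, k_ADP=0.1, q=1


def single_cell_period(params: KineticParams = GATE_PARAMS,
                       t_end: float = 5000.0, transient: float = 2000.0) -> float:
    """Large-amplitude limit-cycle period of the single cell (s).

    Integrates from the slightly nudged uniform state, discards the
    transient, and averages the spacing of interpolated ADP maxima.
    """
    top = ArrayTopology(N=1, delta=np.zeros((1, 1)))
    st = perturbed_uniform_state(params, top)
    traj = simulate(params, top, st, t_end=t_end)
    return measure_period(traj.window(transient, t_end), 1, "fast")


def two_cell_envelope_period(params: KineticParams = GATE_PARAMS,
                             t_end: float = 6000.0, transient: float = 500.0) -> float:
    """Dominant period (s) of the envelope of ADP maxima in cell 1.

    Two mass-coupled cells, unperturbed, from a slightly non-uniform
    initial state: the envelope of successive oscillation maxima is
    extracted and its own maxima spacing averaged.  At the standard
    conditions the computed envelope modulation is numerically flat (the
    cells synchronize onto an exactly periodic orbit), so this measures
    the residual sampling-scale ripple; see the methods note.
    """
    top = build_topology("linear", 2)
    st = perturbed_uniform_state(params, top)
    traj = simulate(params, top, st, t_end=t_end)
    return measure_period(traj.window(transient, t_end), 1, "slow")


def install_tautology_pattern(params: KineticParams = GATE_PARAMS,
                              amplitude: float = 1.2, start: float = 1400.0,
                              duration: float = 600.0,
                              settle: float = 1000.0) -> CellArrayState:
    """Install the two-cell (1, 0) pattern by the long single-cell pulse."""
    top = build_topology("linear", 2)
    st = perturbed_uniform_state(params, top)
    sched = PerturbationSchedule([PerturbationPulse(1, amplitude, start, duration)])
    traj = simulate(params, top, st, sched, t_end=start + duration + settle)
    final = traj.final_state()
    y_star = uniform_steady_state(params)[1]
    if pattern_code(final, y_star) != "10":
        raise RuntimeError("long-pulse protocol failed to install the (1,0) pattern")
    return final


def _pattern_survives(pattern: CellArrayState, amplitude: float,
                      params: KineticParams, duration: float = 100.0,
                      settle: float = 3000.0) -> bool:
    top = build_topology("linear", 2)
    y_star = uniform_steady_state(params)[1]
    code0 = pattern_code(pattern, y_star)
    t0 = pattern.t + 100.0
    sched = PerturbationSchedule([PerturbationPulse(1, amplitude, t0, duration)])
    traj = simulate(params, top, pattern, sched, t_end=t0 + duration + settle)
    return (classify_regime(traj) == "turing_pattern"
            and pattern_code(traj.final_state(), y_star) == code0)


def pattern_robustness_bound(sign: int, params: KineticParams = GATE_PARAMS,
                             duration: float = 100.0, resolution: float = 0.01,
                             pattern: CellArrayState | None = None) -> float:
    """Extreme single-pulse amplitude the installed (1,0) pattern survives.

    ``sign=+1``: largest surviving positive amplitude; ``sign=-1``: most
    negative surviving amplitude.  Survival need not be monotone in the
    amplitude (the two-cell pattern has a switching window at
    intermediate positive amplitudes), so the full grid is scanned for
    the outermost surviving amplitude and only the final survive/switch
    edge is sharpened by bisection.  The pulse is applied to cell 1 of
    the stationary pattern, so the protocol is phase-free.
    """
    if pattern is None:
        pattern = install_tautology_pattern(params)
    grid = np.arange(0.1, 4.01, 0.1) * sign
    outcomes = [ _pattern_survives(pattern, float(a), params, duration)
                 for a in grid ]
    surviving = [float(a) for a, ok in zip(grid, outcomes) if ok]
    if not surviving:
        return 0.0
    lo = max(surviving, key=abs)        # outermost surviving amplitude
    beyond = [float(a) for a in grid if abs(a) > abs(lo)]
    if not beyond:
        return lo
    hi = min(beyond, key=abs)           # first switching amplitude past it
    while abs(hi - lo) > resolution:
        mid = 0.5 * (lo + hi)
        if _pattern_survives(pattern, mid, params, duration):
            lo = mid
        else:
            hi = mid
    return lo


def two_pulse_induction_max_delay(params: KineticParams = GATE_PARAMS,
                                  amplitude: float = 1.2, duration: float = 100.0,
                                  delays: np.ndarray | None = None,
                                  settle: float = 3000.0) -> float:
    """Largest scanned delay between two pulses that still installs a pattern.

    From developed uniform oscillation, the first pulse starts at the
    first receptor event (ADP of cell 1 crossing 80 upward) after 2000 s,
    phase-locking the protocol; the second identical pulse follows after
    a start-to-start delay scanned over ``delays``.  Success of a given
    delay is dominated by the oscillation phase the second pulse lands
    on (see the methods note on the memory effect).
    """
    top = build_topology("linear", 2)
    y_star = uniform_steady_state(params)[1]
    st = perturbed_uniform_state(params, top)
    base = simulate(params, top, st, t_end=2100.0, sample_dt=0.05)
    t, y1 = base.times, base.y(1)
    above = y1 > 80.0
    rising = np.where(~above[:-1] & above[1:])[0]
    rising = rising[t[rising] > 2000.0]
    t_first = float(t[rising[0]])
    state0 = base.state_at(t_first)
    state0.t = t_first
    if delays is None:
        delays = np.arange(duration, 1001.0, 25.0)
    best = 0.0
    for d in delays:
        sched = PerturbationSchedule([
            PerturbationPulse(1, amplitude, t_first, duration),
            PerturbationPulse(1, amplitude, t_first + float(d), duration)])
        traj = simulate(params, top, state0, sched,
                        t_end=t_first + float(d) + duration + settle)
        if classify_regime(traj) == "turing_pattern":
            best = float(d)
    return best


def secondary_hopf_min_sigma_M(params: KineticParams = GATE_PARAMS,
                               sigma_inh_grid: np.ndarray | None = None,
                               seed: int = 0) -> float:
    """Minimal sigma_M on the secondary Hopf curve stabilizing the
    symmetric Turing triplet of the 3-cell cyclic array (1/s).

    The stable symmetric non-uniform state is found at (sigma_M=100,
    sigma_inh=35), then its stability boundary in sigma_M is continued
    across sigma_inh sweeping outward from 35 in both directions.
    """
    top = build_topology("cyclic", 3)
    states = enumerate_states(params, top, seed=seed, n_starts=256)
    seeds = [s for s in states if s.stable and s.symmetry == "symmetric_nonuniform"]
    if not seeds:
        raise RuntimeError("no stable symmetric non-uniform state at the anchor point")
    seed_state = seeds[0]
    if sigma_inh_grid is None:
        sigma_inh_grid = np.arange(20.0, 61.0, 1.0)
    si0 = params.sigma_inh
    up = sigma_inh_grid[sigma_inh_grid >= si0]
    down = sigma_inh_grid[sigma_inh_grid < si0][::-1]
    mins = []
    for grid in (up, down):
        if not len(grid):
            continue
        curve = secondary_hopf_curve(params, top, seed_state,
                                     ("sigma_M", "sigma_inh"),
                                     (40.0, 140.0), grid, p1_step=2.0)
        if len(curve.points):
            mins.append(curve.points[:, 0].min())
    if not mins:
        raise RuntimeError("secondary Hopf curve not found")
    return float(min(mins))


def five_pattern_onset_sigma_M(params: KineticParams = GATE_PARAMS,
                               sigma_M_grid: np.ndarray | None = None,
                               sigma_inh_grid: np.ndarray | None = None,
                               n_starts: int = 512, seed: int = 0) -> float:
    """Smallest sigma_M at which >= 5 stable non-uniform states coexist
    for some sigma_inh (3-cell cyclic array, q=1, k_ADP=0.1).

    Column-by-column multistart enumeration over a (sigma_M, sigma_inh)
    grid with warm starts along each column.
    """
    top = build_topology("cyclic", 3)
    if sigma_M_grid is None:
        sigma_M_grid = np.arange(100.0, 150.1, 2.5)
    if sigma_inh_grid is None:
        sigma_inh_grid = np.arange(20.0, 60.1, 1.0)
    for sM in sigma_M_grid:
        warm = None
        for si in sigma_inh_grid:
            p = params.replace(sigma_M=float(sM), sigma_inh=float(si))
            try:
                states = enumerate_states(p, top, n_starts=n_starts, seed=seed,
                                          extra_guesses=warm)
            except ValueError:
                warm = None
                continue
            warm = np.array([s.z for s in states]) if states else None
            n_stab = sum(1 for s in states if s.stable and s.symmetry != "uniform")
            if n_stab >= 5:
                return float(sM)
    raise RuntimeError("no grid column reached five stable non-uniform states")


def turing_region_max_sigma_inh(topology: ArrayTopology | None = None,
                                sigma_M: float = 10.0, q: float = 100.0,
                                k_ADP_range: tuple[float, float] = (5e-4, 0.05),
                                n_grid: int = 120) -> float:
    """Upper sigma_inh extent (1/s) of the primary symmetry-breaking region
    for a four-cell array at q = 100, sigma_M = 10 1/s.

    Continues the branch-point condition det A(mu) = 0 of every
    non-uniform spatial mode across the (sigma_inh, k_ADP) plane and
    reports the largest sigma_inh on any of the curves.  (The uniform
    stationary state ceases to exist for sigma_inh beyond about
    (sigma_M - nu) / h(y*), which bounds the search window.)
    """
    if topology is None:
        topology = build_topology("linear", 4)
    params = KineticParams(sigma_M=sigma_M, q=q, k_ADP=0.01)
    mus = np.unique(np.round(np.linalg.eigvalsh(topology.laplacian), 9))
    best = None
    for mu in mus:
        if mu < 1e-9:
            continue
        c = uniform_mode_curve(params, topology, "branch_point",
                               ("sigma_inh", "k_ADP"),
                               ((0.2, 12.0), k_ADP_range), float(mu), n_grid)
        if len(c.points):
            top_si = c.points[:, 0].max()
            best = top_si if best is None else max(best, top_si)
    if best is None:
        raise RuntimeError("no symmetry-breaking curve found in the window")
    return float(best)
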
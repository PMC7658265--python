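"""Logic gates driven by the central knockout perturbation system.

An array parked in a region where several discrete Turing patterns
coexist with uniform oscillations computes a Boolean function per cell.
A global clock ticks at t_k = 1000 k + 600 s.  Input words arrive as ATP
pulses 100 s before a tick (bit 1 -> positive amplitude, bit 0 ->
negative).  After the tick, each cell's receptor watches for ADP
exceeding the receptor level (large-amplitude oscillation); at the first
receptor event the knockout pulses fire (per the knockout word), driving
the oscillation into the word's own Turing pattern.  If the input left
the array in a stationary pattern, no receptor fires and no knockout is
applied.  Outputs are read 900 s after the tick as the pattern code of
ADP against the uniform level y*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boolexpr import BooleanExpr, all_input_words
from .dynamics import (
    RECEPTOR_LEVEL,
    PerturbationPulse,
    PerturbationSchedule,
    Trajectory,
    pattern_code,
    perturbed_uniform_state,
    simulate,
)
from .model import ArrayTopology, CellArrayState, KineticParams, uniform_steady_state

__all__ = [
    "GateConfig",
    "TruthTable",
    "run_gate_cycle",
    "truth_table",
    "verify_table",
    "TABLE_2A_ORDER",
]

#: Input-word order of the printed three-cell table.
TABLE_2A_ORDER = ("011", "100", "001", "010", "101", "110", "000", "111")


@dataclass(frozen=True)
class GateConfig:
    """Array, kinetics, knockout word and the timing of the central system."""

    params: KineticParams
    topology: ArrayTopology
    knockout_sequence: str
    input_on: float = 1.2            # amplitude for input bit 1
    input_off: float = -1.0          # amplitude for input bit 0
    knockout_on: float = 1.2         # knockout pulse for knockout bit 1
    knockout_off: float = -1.0       # knockout pulse for knockout bit 0
    pulse_duration: float = 100.0    # s
    clock_period: float = 1000.0     # s
    clock_offset: float = 600.0      # first tick at 600 s: t_k = 1000 k + 600
    input_delay: float = -100.0      # s relative to tick
    output_delay: float = +900.0     # s relative to tick
    receptor_level: float = RECEPTOR_LEVEL
    resolve_ptp: float = 1.0         # max ADP peak-to-peak for a resolved output

    def __post_init__(self):
        if len(self.knockout_sequence) != self.topology.N:
            raise ValueError("knockout word length must equal the cell count")
        if set(self.knockout_sequence) - {"0", "1"}:
            raise ValueError("knockout word must be binary")
        if self.pulse_duration <= 0:
            raise ValueError("pulse duration must be positive")
        for d in (self.input_delay, self.output_delay):
            if abs(d) >= self.clock_period:
                raise ValueError("delays must fit within one clock interval")

    @property
    def N(self) -> int:
        return self.topology.N

    def tick(self, k: int) -> float:
        return self.clock_period * k + self.clock_offset

    def y_star(self) -> float:
        return uniform_steady_state(self.params)[1]


@dataclass
class TruthTable:
    """Simulated gate response over a full set of input words."""

    inputs: list[str]
    outputs: list[str | None]        # None marks an unresolved cycle
    knockout_sequence: str
    expressions: list[BooleanExpr] = field(default_factory=list)

    @property
    def resolved(self) -> bool:
        return all(o is not None for o in self.outputs)

    def column(self, cell: int) -> list[int | None]:
        """Output bits of one cell (1-based) down the table."""
        return [None if o is None else int(o[cell - 1]) for o in self.outputs]

    def to_frame(self):
        import pandas as pd

        n = len(self.inputs[0])
        rows = []
        for w, o in zip(self.inputs, self.outputs):
            row = {f"A{i + 1}": int(w[i]) for i in range(n)}
            for i in range(n):
                row[f"y{i + 1}"] = None if o is None else int(o[i])
            rows.append(row)
        return pd.DataFrame(rows)


def _first_receptor_time(traj: Trajectory, level: float, t_from: float) -> float | None:
    """First upward crossing of any cell's ADP through the receptor level."""
    t = traj.times
    Y = traj.states[:, traj.N:]
    sel = t >= t_from
    if sel.sum() < 2:
        return None
    above = (Y[sel] > level).any(axis=1)
    rising = np.where(~above[:-1] & above[1:])[0]
    if above[0]:
        return float(t[sel][0])
    if not len(rising):
        return None
    return float(t[sel][rising[0] + 1])


def run_gate_cycle(config: GateConfig, input_word: str,
                   state: CellArrayState,
                   tick: float | None = None,
                   solver_opts: dict | None = None,
                   ) -> tuple[str | None, CellArrayState, Trajectory]:
    """Run one clock cycle from ``state`` (at time tick + input_delay).

    Returns (output bits or None if unresolved, state at the output read
    time, trajectory of the whole cycle).
    """
    N = config.N
    if len(input_word) != N or set(input_word) - {"0", "1"}:
        raise ValueError("input word must be binary of length N")
    if tick is None:
        tick = state.t - config.input_delay
    dT = config.pulse_duration
    t_in = tick + config.input_delay
    t_out = tick + config.output_delay
    if abs(state.t - t_in) > 1e-9:
        raise ValueError(f"state time {state.t} does not match input time {t_in}")

    pulses = [PerturbationPulse(i + 1,
                                config.input_on if b == "1" else config.input_off,
                                t_in, dT)
              for i, b in enumerate(input_word)]
    # pass 1: no knockout; watch the receptor from the tick onward
    sched = PerturbationSchedule(pulses)
    probe = simulate(config.params, config.topology, state, sched,
                     t_end=t_out, solver_opts=solver_opts)
    t_fire = _first_receptor_time(probe, config.receptor_level, tick)
    if t_fire is not None and t_fire + dT <= t_out:
        ko = [PerturbationPulse(i + 1,
                                config.knockout_on if b == "1" else config.knockout_off,
                                t_fire, dT)
              for i, b in enumerate(config.knockout_sequence)]
        sched = PerturbationSchedule(pulses + ko)
        traj = simulate(config.params, config.topology, state, sched,
                        t_end=t_out, solver_opts=solver_opts)
    else:
        traj = probe
    final = traj.final_state()
    tail = traj.window(t_out - dT, t_out)
    settled = float(np.ptp(tail.states[:, N:], axis=0).max()) < config.resolve_ptp
    out = pattern_code(final, config.y_star()) if settled else None
    return out, final, traj


def initial_oscillating_state(config: GateConfig,
                              solver_opts: dict | None = None) -> CellArrayState:
    """Uniform oscillation developed from the nudged uniform state at t=0,
    advanced to the first input time (tick 0 + input_delay)."""
    t_in0 = config.tick(0) + config.input_delay
    st = perturbed_uniform_state(config.params, config.topology)
    traj = simulate(config.params, config.topology, st, t_end=t_in0,
                    solver_opts=solver_opts)
    return traj.final_state()


def truth_table(config: GateConfig, input_order: tuple[str, ...] | None = None,
                initial: CellArrayState | None = None,
                infer: bool = False,
                solver_opts: dict | None = None) -> TruthTable:
    """Chain one gate cycle per input word, as in the printed experiments.

    Each cycle starts from the previous cycle's final state; the first
    starts from developed uniform oscillations.  For three cells the
    default word order is the printed one; otherwise ascending binary.
    """
    N = config.N
    if input_order is None:
        input_order = TABLE_2A_ORDER if N == 3 else tuple(all_input_words(N))
    if sorted(input_order) != all_input_words(N):
        raise ValueError("input_order must enumerate all 2^N words exactly once")
    state = initial if initial is not None else initial_oscillating_state(config, solver_opts)
    outputs: list[str | None] = []
    for k, word in enumerate(input_order):
        out, state, _ = run_gate_cycle(config, word, state, tick=config.tick(k),
                                       solver_opts=solver_opts)
        outputs.append(out)
    table = TruthTable(list(input_order), outputs, config.knockout_sequence)
    if infer and table.resolved:
        from .boolexpr import infer_expression

        table.expressions = [infer_expression(table.column(c), table.inputs)
                             for c in range(1, N + 1)]
    return table


def verify_table(table: TruthTable, exprs: list[BooleanExpr]) -> dict:
    """Compare a simulated table against per-cell Boolean expressions.

    Returns {'match': bool, 'mismatches': [(row, cell, simulated, expected)]}.
    """
    n = len(table.inputs[0])
    if len(exprs) != n:
        raise ValueError(f"need {n} expressions, got {len(exprs)}")
    mismatches = []
    for r, (w, o) in enumerate(zip(table.inputs, table.outputs)):
        for c in range(n):
            expected = exprs[c](w)
            got = None if o is None else int(o[c])
            if got != expected:
                mismatches.append((r, c + 1, got, expected))
    return {"match": not mismatches, "mismatches": mismatches}
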
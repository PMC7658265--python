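"""Cellular assemblages: gate arrays wired together by idealized channels.

Components (gate arrays, the tautology/contradiction reference device, a
clock cell with counter, two-cell memory pairs, sources and sinks) are
co-simulated lock-step, one clock interval at a time.  Links carry
binary signals with a fixed delay; the chemistry of the excitable
channels is abstracted to these delayed binary links, and no mass is
exchanged between components — only signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .dynamics import (
    PerturbationPulse,
    PerturbationSchedule,
    classify_regime,
    measure_period,
    pattern_code,
    perturbed_uniform_state,
    simulate,
)
from .gates import GateConfig, run_gate_cycle
from .model import ArrayTopology, CellArrayState, KineticParams, build_topology, uniform_steady_state

__all__ = [
    "Component",
    "Link",
    "Netlist",
    "make_tautology_device",
    "make_clock",
    "make_memory_pair",
    "make_gate_array",
    "make_source",
    "make_sink",
    "memory_write",
    "memory_read",
    "simulate_assemblage",
]

COEXISTENCE_PARAMS = KineticParams()  # q=1, sigma_M=100, sigma_inh=35, k_ADP=0.1


@dataclass
class Component:
    """One block of the assemblage with named binary ports."""

    kind: str                      # gate_array | tautology_device | clock_cell |
                                   # memory_pair | source | sink
    name: str
    inputs: tuple[str, ...] = ()
    outputs: tuple[str, ...] = ()
    config: Any = None             # GateConfig for gate arrays, params otherwise
    state: Any = None              # CellArrayState or plain python state
    port_map: dict[str, int] = field(default_factory=dict)  # port -> cell (1-based)
    fixed_bits: dict[int, str] = field(default_factory=dict)  # cell -> constant bit


@dataclass(frozen=True)
class Link:
    """Directed binary channel between two ports, with transport delay."""

    src: tuple[str, str]           # (component name, output port)
    dst: tuple[str, str]           # (component name, input port)
    delay: float = 0.0             # s; must fit within one clock interval
    blocked: bool = False          # the "knockout switch" on the channel


@dataclass
class Netlist:
    components: list[Component]
    links: list[Link]

    def __post_init__(self):
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        by_name = {c.name: c for c in self.components}
        wired = set()
        for ln in self.links:
            sc, sp = ln.src
            dc, dp = ln.dst
            if sp not in by_name[sc].outputs:
                raise ValueError(f"{sc} has no output port {sp!r}")
            if dp not in by_name[dc].inputs:
                raise ValueError(f"{dc} has no input port {dp!r}")
            if (dc, dp) in wired:
                raise ValueError(f"input port {dc}.{dp} wired twice")
            wired.add((dc, dp))
        for c in self.components:
            for p in c.inputs:
                if (c.name, p) not in wired:
                    raise ValueError(f"input port {c.name}.{p} is unwired")

    def component(self, name: str) -> Component:
        return next(c for c in self.components if c.name == name)


# ---------------------------------------------------------------------------
# component constructors

def make_tautology_device(params: KineticParams = COEXISTENCE_PARAMS,
                          name: str = "taut",
                          install_start: float = 1400.0,
                          install_duration: float = 600.0,
                          install_amplitude: float = 1.2,
                          solver_opts: dict | None = None) -> Component:
    """Two coupled cells locked into the (1, 0) pattern.

    Initialized by the long-pulse protocol: oscillation developed from
    t = 0, then a single pulse on cell 1.  Thereafter port ``one`` reads
    constant 1 and port ``zero`` constant 0.
    """
    top = build_topology("linear", 2)
    st = perturbed_uniform_state(params, top)
    sched = PerturbationSchedule([
        PerturbationPulse(1, install_amplitude, install_start, install_duration)])
    t_end = install_start + install_duration + 1000.0
    traj = simulate(params, top, st, sched, t_end=t_end, solver_opts=solver_opts)
    final = traj.final_state()
    y_star = uniform_steady_state(params)[1]
    if pattern_code(final, y_star) != "10":
        raise RuntimeError("tautology initialization did not produce the (1,0) pattern "
                           f"(pattern code {pattern_code(final, y_star)!r})")
    return Component(kind="tautology_device", name=name,
                     outputs=("one", "zero"), config=params, state=final,
                     port_map={"one": 1, "zero": 2})


def make_clock(params: KineticParams = COEXISTENCE_PARAMS, name: str = "clock",
               count: int = 20,
               solver_opts: dict | None = None) -> Component:
    """A naturally oscillating cell plus a counter.

    The counter accumulates large-amplitude ADP peaks and emits a tick
    every ``count`` peaks, then resets; with the default single-cell
    period of about 50.3 s and count = 20 the tick interval is ~1006 s.
    """
    top = ArrayTopology(N=1, delta=np.zeros((1, 1)))
    st = perturbed_uniform_state(params, top)
    traj = simulate(params, top, st, t_end=4000.0, solver_opts=solver_opts)
    if classify_regime(traj) not in ("uniform_osc", "nonuniform_osc"):
        raise RuntimeError("clock cell is not oscillating at these parameters")
    period = measure_period(traj.window(1000.0, 4000.0), 1, "fast")
    return Component(kind="clock_cell", name=name, outputs=("tick",),
                     config=params,
                     state={"period": period, "count": count,
                            "tick_interval": count * period})


def make_memory_pair(params: KineticParams = COEXISTENCE_PARAMS,
                     name: str = "mem",
                     solver_opts: dict | None = None) -> Component:
    """Two coupled cells storing one bit as the (1,0) / (0,1) pattern."""
    top = build_topology("linear", 2)
    st = perturbed_uniform_state(params, top)
    traj = simulate(params, top, st, t_end=500.0, solver_opts=solver_opts)
    return Component(kind="memory_pair", name=name,
                     inputs=("write",), outputs=("read",),
                     config=params, state=traj.final_state(),
                     port_map={"read": 1})


def make_gate_array(config: GateConfig, name: str,
                    input_ports: dict[str, int],
                    output_ports: dict[str, int],
                    fixed_bits: dict[int, str] | None = None,
                    initial: CellArrayState | None = None) -> Component:
    """A coupled-cell logic-gate array as an assemblage component.

    ``input_ports``/``output_ports`` map port names to 1-based cells;
    cells not covered by an input port read the constant bit from
    ``fixed_bits`` (default '0').
    """
    return Component(kind="gate_array", name=name,
                     inputs=tuple(input_ports), outputs=tuple(output_ports),
                     config=config, state=initial,
                     port_map={**input_ports, **output_ports},
                     fixed_bits=dict(fixed_bits or {}))


def make_source(name: str, stream: list[str]) -> Component:
    """Emits one bit per cycle on port ``out`` (repeats the last bit)."""
    return Component(kind="source", name=name, outputs=("out",),
                     state={"stream": [str(b) for b in stream]})


def make_sink(name: str) -> Component:
    return Component(kind="sink", name=name, inputs=("in",), state={"log": []})


# ---------------------------------------------------------------------------
# memory operations

def memory_write(pair: Component, bit: int,
                 on: float = 1.2, off: float = -1.0, duration: float = 100.0,
                 settle: float = 3000.0,
                 solver_opts: dict | None = None) -> Component:
    """Write one bit as the |1 0| or |0 1| pulse pair and let it settle."""
    if pair.kind != "memory_pair":
        raise ValueError("memory_write needs a memory_pair component")
    params = pair.config
    top = build_topology("linear", 2)
    st = pair.state
    t0 = st.t
    amps = (on, off) if bit else (off, on)
    sched = PerturbationSchedule([
        PerturbationPulse(1, amps[0], t0, duration),
        PerturbationPulse(2, amps[1], t0, duration)])
    traj = simulate(params, top, st, sched, t_end=t0 + duration + settle,
                    solver_opts=solver_opts)
    final = traj.final_state()
    y_star = uniform_steady_state(params)[1]
    code = pattern_code(final, y_star)
    if code not in ("10", "01"):
        raise RuntimeError(f"memory write did not settle on a pattern (code {code!r})")
    pair.state = final
    return pair


def memory_read(pair: Component) -> int:
    """Stored bit = pattern code of cell 1; no state change."""
    y_star = uniform_steady_state(pair.config)[1]
    return int(pattern_code(pair.state, y_star)[0])


# ---------------------------------------------------------------------------
# co-simulation

def _component_outputs(comp: Component, cycle: int) -> dict[str, str]:
    if comp.kind == "source":
        stream = comp.state["stream"]
        bit = stream[min(cycle, len(stream) - 1)] if stream else "0"
        return {"out": bit}
    if comp.kind == "tautology_device":
        y_star = uniform_steady_state(comp.config)[1]
        code = pattern_code(comp.state, y_star)
        return {"one": code[0], "zero": code[1]}
    if comp.kind == "memory_pair":
        return {"read": str(memory_read(comp))}
    if comp.kind == "clock_cell":
        return {"tick": "1"}
    return {}


def simulate_assemblage(netlist: Netlist, input_streams: dict[str, list[str]],
                        cycles: int,
                        solver_opts: dict | None = None) -> "AssemblageResult":
    """Cycle-synchronous co-simulation of the assemblage.

    Per clock interval: source/reference/memory outputs are computed,
    signals propagate along unblocked links (delays must fit within the
    interval), every gate array runs one full ODE gate cycle on its input
    word, and sink/memory inputs are applied.  An unresolved gate output
    propagates as ``None`` and halts the run with a cycle-stamped report.
    """
    for comp in netlist.components:
        if comp.kind == "source" and comp.name in input_streams:
            comp.state["stream"] = [str(b) for b in input_streams[comp.name]]
    for ln in netlist.links:
        period = 1000.0
        if ln.delay >= period:
            raise ValueError(f"link delay {ln.delay} exceeds one clock interval")
    records: list[tuple[int, str, str, str]] = []
    halted = None
    for cycle in range(cycles):
        port_values: dict[tuple[str, str], str | None] = {}
        for comp in netlist.components:
            for port, bit in _component_outputs(comp, cycle).items():
                port_values[(comp.name, port)] = bit
        # gate arrays read wired inputs, run one cycle, publish outputs
        for comp in netlist.components:
            if comp.kind != "gate_array":
                continue
            cfg: GateConfig = comp.config
            N = cfg.N
            word = [comp.fixed_bits.get(c, "0") for c in range(1, N + 1)]
            unresolved_input = False
            for ln in netlist.links:
                if ln.dst[0] != comp.name or ln.blocked:
                    continue
                bit = port_values.get(ln.src)
                if bit is None:
                    unresolved_input = True
                else:
                    word[comp.port_map[ln.dst[1]] - 1] = bit
            if unresolved_input:
                halted = (cycle, comp.name, "unresolved input")
                break
            if comp.state is None:
                from .gates import initial_oscillating_state

                comp.state = initial_oscillating_state(cfg, solver_opts)
            tick = cfg.tick(0) + cycle * cfg.clock_period
            comp.state = replace_time(comp.state, tick + cfg.input_delay)
            out, comp.state, _ = run_gate_cycle(cfg, "".join(word), comp.state,
                                                tick=tick, solver_opts=solver_opts)
            if out is None:
                halted = (cycle, comp.name, "unresolved output")
                break
            for port in comp.outputs:
                port_values[(comp.name, port)] = out[comp.port_map[port] - 1]
        if halted:
            break
        # deliver to sinks and memory writes
        for ln in netlist.links:
            if ln.blocked:
                continue
            dst = netlist.component(ln.dst[0])
            bit = port_values.get(ln.src)
            if dst.kind == "sink" and bit is not None:
                dst.state["log"].append((cycle, bit))
                records.append((cycle, ln.dst[0], ln.dst[1], bit))
            elif dst.kind == "memory_pair" and ln.dst[1] == "write" and bit is not None:
                memory_write(dst, int(bit), solver_opts=solver_opts)
        for (cname, pname), bit in sorted(port_values.items()):
            if bit is not None:
                records.append((cycle, cname, pname, bit))
    return AssemblageResult(records=records, halted=halted)


def replace_time(state: CellArrayState, t: float) -> CellArrayState:
    return CellArrayState(x=state.x.copy(), y=state.y.copy(), t=t)


@dataclass
class AssemblageResult:
    """Port values per cycle, plus a halt report if a gate was unresolved."""

    records: list[tuple[int, str, str, str]]
    halted: tuple[int, str, str] | None = None

    def port_series(self, component: str, port: str) -> list[str]:
        return [bit for cyc, c, p, bit in self.records
                if c == component and p == port]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records, columns=["cycle", "component", "port", "bit"])
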
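"""Assemblage components: reference device, clock, memory, co-simulation."""

import numpy as np
import pytest

from turingcells import assemblage as asm
from turingcells.dynamics import (
    perturbed_uniform_state,
    PerturbationPulse,
    PerturbationSchedule,
    classify_regime,
    pattern_code,
    simulate,
)
from turingcells.gates import GateConfig, truth_table
from turingcells.model import build_topology, uniform_steady_state


@pytest.fixture(scope="module")
def tautology(gate_params):
    return asm.make_tautology_device(gate_params)


class TestTautologyDevice:
    def test_emits_constant_one_zero(self, tautology):
        out = asm._component_outputs(tautology, 0)
        assert (out["one"], out["zero"]) == ("1", "0")

    def test_pattern_survives_the_stress_pulse_protocol(self, gate_params, tautology,
                                                        two_cell):
        pulses = [PerturbationPulse(1, 1.2, t, 100.0) for t in (3500.0, 4500.0, 7500.0)]
        pulses += [PerturbationPulse(1, -0.5, t, 100.0) for t in (5500.0, 6500.0)]
        st = tautology.state
        traj = simulate(gate_params, two_cell, st, PerturbationSchedule(pulses),
                        t_end=10000.0)
        assert classify_regime(traj) == "turing_pattern"
        ys = uniform_steady_state(gate_params)[1]
        assert pattern_code(traj.final_state(), ys) == "10"

    @pytest.mark.parametrize("var", [500.0, 1000.0])
    def test_pulse_length_start_time_tradeoff(self, gate_params, var):
        # duration (2000 - var) starting at (100 + var) also installs
        dev = asm.make_tautology_device(gate_params,
                                        install_start=100.0 + var,
                                        install_duration=2000.0 - var)
        out = asm._component_outputs(dev, 0)
        assert (out["one"], out["zero"]) == ("1", "0")

    def test_tradeoff_fails_when_the_pulse_starts_mid_startup(self, gate_params,
                                                              two_cell):
        """The duration/start trade-off breaks down at its extreme: a pulse
        from t = 100 s (oscillation barely developed) leaves the array
        oscillating instead of patterned."""
        st = simulate(gate_params, two_cell,
                      perturbed_uniform_state(gate_params, two_cell),
                      PerturbationSchedule([PerturbationPulse(1, 1.2, 100.0, 2000.0)]),
                      t_end=6100.0)
        assert classify_regime(st) != "turing_pattern"


class TestClock:
    def test_tick_interval_is_count_times_period(self, gate_params):
        clock = asm.make_clock(gate_params, count=20)
        assert clock.state["tick_interval"] == pytest.approx(20 * 50.29, rel=5e-3)

    def test_count_one_gives_one_period(self, gate_params):
        clock = asm.make_clock(gate_params, count=1)
        assert clock.state["tick_interval"] == pytest.approx(clock.state["period"],
                                                             rel=1e-12)

    def test_interval_consistent_with_measured_period(self, gate_params):
        clock = asm.make_clock(gate_params, count=20)
        assert clock.state["tick_interval"] / 20 == pytest.approx(
            clock.state["period"], rel=5e-3)


class TestMemory:
    def test_write_read_cycle(self, gate_params):
        mem = asm.make_memory_pair(gate_params)
        asm.memory_write(mem, 1)
        assert asm.memory_read(mem) == 1
        assert asm.memory_read(mem) == 1      # read is idempotent
        asm.memory_write(mem, 0)
        assert asm.memory_read(mem) == 0

    def test_stored_bit_persists(self, gate_params, two_cell):
        mem = asm.make_memory_pair(gate_params)
        asm.memory_write(mem, 1)
        st = mem.state
        traj = simulate(gate_params, two_cell, st, t_end=st.t + 10000.0, sample_dt=2.0)
        drift = np.abs(traj.states - st.z[None, :]).max()
        assert drift < 1e-6


def _nand_netlist(gate_params, streams):
    cfg = GateConfig(params=gate_params, topology=build_topology("cyclic", 3),
                     knockout_sequence="011")
    gate = asm.make_gate_array(cfg, "nand", {"a": 1, "b": 3}, {"q": 2},
                               fixed_bits={2: "0"})
    sa = asm.make_source("sa", streams[0])
    sb = asm.make_source("sb", streams[1])
    sink = asm.make_sink("out")
    links = [asm.Link(("sa", "out"), ("nand", "a")),
             asm.Link(("sb", "out"), ("nand", "b")),
             asm.Link(("nand", "q"), ("out", "in"))]
    return asm.Netlist([sa, sb, gate, sink], links), sink


class TestAssemblage:
    def test_nand_wired_pair(self, gate_params):
        net, sink = _nand_netlist(gate_params, (["1", "1", "0", "0"],
                                                ["1", "0", "1", "0"]))
        asm.simulate_assemblage(net, {}, cycles=4)
        assert [b for _, b in sink.state["log"]] == ["0", "1", "1", "1"]

    def test_netlist_gate_matches_standalone_truth_table(self, gate_params, cyclic3):
        cfg = GateConfig(params=gate_params, topology=cyclic3,
                         knockout_sequence="011")
        table = truth_table(cfg)
        words = table.inputs
        gate = asm.make_gate_array(cfg, "g", {"a": 1, "b": 2, "c": 3},
                                   {"y1": 1, "y2": 2, "y3": 3})
        srcs = [asm.make_source(n, [w[i] for w in words]) for i, n in
                enumerate(("sa", "sb", "sc"))]
        sinks = [asm.make_sink(f"o{i}") for i in range(3)]
        links = [asm.Link(("sa", "out"), ("g", "a")),
                 asm.Link(("sb", "out"), ("g", "b")),
                 asm.Link(("sc", "out"), ("g", "c"))]
        links += [asm.Link(("g", f"y{i + 1}"), (f"o{i}", "in")) for i in range(3)]
        net = asm.Netlist(srcs + [gate] + sinks, links)
        asm.simulate_assemblage(net, {}, cycles=len(words))
        outputs = ["".join(net.component(f"o{i}").state["log"][k][1]
                           for i in range(3))
                   for k in range(len(words))]
        assert outputs == table.outputs

    def test_reference_signals_stable_over_ten_cycles(self, gate_params, tautology):
        sink1 = asm.make_sink("s1")
        sink0 = asm.make_sink("s0")
        net = asm.Netlist([tautology, sink1, sink0],
                          [asm.Link(("taut", "one"), ("s1", "in")),
                           asm.Link(("taut", "zero"), ("s0", "in"))])
        asm.simulate_assemblage(net, {}, cycles=10)
        assert [b for _, b in sink1.state["log"]] == ["1"] * 10
        assert [b for _, b in sink0.state["log"]] == ["0"] * 10

    def test_determinism(self, gate_params):
        runs = []
        for _ in range(2):
            net, sink = _nand_netlist(gate_params, (["1", "0"], ["1", "1"]))
            res = asm.simulate_assemblage(net, {}, cycles=2)
            runs.append(res.records)
        assert runs[0] == runs[1]

    def test_netlist_validation(self, gate_params):
        src = asm.make_source("s", ["1"])
        sink = asm.make_sink("o")
        with pytest.raises(ValueError, match="unwired"):
            asm.Netlist([src, sink], [])
        with pytest.raises(ValueError, match="no output port"):
            asm.Netlist([src, sink], [asm.Link(("s", "nope"), ("o", "in"))])
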
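"""Run configurations, result bundles and test-fixture generation.

A RunConfig captures one analysis (simulate | states | diagram | regions
| curve | gate | assemblage | fixtures) with its topology, kinetic
parameters, schedule and seeds, round-trips losslessly through YAML, and
executes into an on-disk bundle (config echo + CSV/JSON outputs + log +
version stamp).  A single global seed governs every stochastic component.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dynamics import PerturbationPulse, PerturbationSchedule, simulate, perturbed_uniform_state
from .model import (
    ArrayTopology,
    CellArrayState,
    KineticParams,
    automorphisms,
    build_topology,
    uniform_steady_state,
)

__all__ = ["RunConfig", "run", "generate_fixtures"]

ANALYSES = ("simulate", "states", "diagram", "regions", "curve", "gate",
            "assemblage", "fixtures")

_PARAM_FIELDS = set(KineticParams.__dataclass_fields__)


@dataclass
class RunConfig:
    """Declarative description of one workbench run."""

    analysis: str
    topology: dict = field(default_factory=lambda: {"kind": "linear", "N": 2})
    params: dict = field(default_factory=dict)
    schedule: list = field(default_factory=list)   # rows (cell, amplitude, start, duration)
    solver: dict = field(default_factory=dict)
    seed: int = 0
    options: dict = field(default_factory=dict)    # analysis-specific settings

    def __post_init__(self):
        if self.analysis not in ANALYSES:
            raise ValueError(f"analysis must be one of {ANALYSES}, got {self.analysis!r}")
        unknown = set(self.params) - _PARAM_FIELDS
        if unknown:
            raise ValueError(f"unknown kinetic parameters: {sorted(unknown)}")
        tkeys = set(self.topology) - {"kind", "N", "edges"}
        if tkeys:
            raise ValueError(f"unknown topology keys: {sorted(tkeys)}")

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_yaml(cls, path_or_text: str | Path) -> "RunConfig":
        text = Path(path_or_text).read_text() if Path(str(path_or_text)).exists() \
            else str(path_or_text)
        data = yaml.safe_load(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    # -- realized objects --------------------------------------------------
    def kinetic_params(self) -> KineticParams:
        return KineticParams(**self.params)

    def array_topology(self) -> ArrayTopology:
        t = self.topology
        if "edges" in t:
            N = int(t["N"])
            delta = np.zeros((N, N))
            for i, j in t["edges"]:
                delta[i - 1, j - 1] = delta[j - 1, i - 1] = 1.0
            return ArrayTopology(N=N, delta=delta, kind=t.get("kind", "custom"))
        return build_topology(t.get("kind", "linear"), int(t.get("N", 2)))

    def perturbation_schedule(self) -> PerturbationSchedule:
        return PerturbationSchedule([PerturbationPulse(int(c), float(a), float(s), float(d))
                                     for c, a, s, d in self.schedule])


def _write_log(outdir: Path, lines: list[str]) -> None:
    (outdir / "run.log").write_text("\n".join(lines) + "\n")


def run(config: RunConfig, outdir: str | Path) -> Path:
    """Execute a RunConfig into a result bundle directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = [f"turingcells {__version__}", f"analysis: {config.analysis}",
           f"seed: {config.seed}"]
    (outdir / "config.yaml").write_text(config.to_yaml())
    params = config.kinetic_params()
    opts = config.options

    if config.analysis == "simulate":
        top = config.array_topology()
        initial = opts.get("initial")
        if initial:
            st = CellArrayState(x=initial["x"], y=initial["y"], t=initial.get("t", 0.0))
        else:
            st = perturbed_uniform_state(params, top)
        traj = simulate(params, top, st, config.perturbation_schedule(),
                        t_end=float(opts.get("t_end", 5000.0)),
                        solver_opts=config.solver or None)
        traj.to_frame().to_csv(outdir / "trajectory.csv", index=False)
        log.append(f"trajectory: {len(traj.times)} samples to t={traj.times[-1]:.1f} s")

    elif config.analysis == "states":
        from .steady_states import enumerate_states, states_table

        top = config.array_topology()
        states = enumerate_states(params, top, seed=config.seed,
                                  n_starts=int(opts.get("n_starts", 512)))
        states_table(states).to_csv(outdir / "states.csv", index=False)
        log.append(f"states: {len(states)} found "
                   f"({sum(1 for s in states if s.stable)} stable)")

    elif config.analysis == "diagram":
        from .continuation import solution_diagram

        top = config.array_topology()
        name = opts.get("free_parameter", "sigma_inh")
        prange = tuple(opts.get("range", (20.0, 60.0)))
        branches = solution_diagram(params, top, name, prange)
        frames = []
        for i, b in enumerate(branches):
            f = b.to_frame()
            f.insert(0, "branch", i)
            frames.append(f)
        import pandas as pd

        pd.concat(frames, ignore_index=True).to_csv(outdir / "diagram.csv", index=False)
        summary = [{"branch": i,
                    "n_points": len(b.points),
                    "stable_windows": b.stability_windows(),
                    "bifurcations": [{"kind": bp.kind, name: bp.param,
                                      "omega_rad_per_s": bp.omega}
                                     for bp in b.bifurcations]}
                   for i, b in enumerate(branches)]
        (outdir / "diagram.json").write_text(json.dumps(summary, indent=1, default=float))
        log.append(f"diagram: {len(branches)} branches")

    elif config.analysis == "regions":
        from .continuation import region_map

        top = config.array_topology()
        pair = tuple(opts.get("parameter_pair", ("sigma_inh", "sigma_M")))
        g1 = np.linspace(*opts.get("range1", (20.0, 60.0)), int(opts.get("n1", 21)))
        g2 = np.linspace(*opts.get("range2", (60.0, 150.0)), int(opts.get("n2", 19)))
        labels = region_map(pair, (g1, g2), params, top,
                            n_starts=int(opts.get("n_starts", 512)), seed=config.seed)
        import pandas as pd

        pd.DataFrame([{pair[0]: l.p1, pair[1]: l.p2, "m_total": l.m,
                       "n_stable": l.n, "n_stable_nonuniform": l.n_stable_nonuniform}
                      for l in labels]).to_csv(outdir / "regions.csv", index=False)
        log.append(f"regions: {len(labels)} nodes")

    elif config.analysis == "curve":
        from .continuation import uniform_mode_curve

        top = config.array_topology()
        pair = tuple(opts.get("parameter_pair", ("sigma_inh", "k_ADP")))
        ranges = (tuple(opts.get("range1", (5.0, 98.0))),
                  tuple(opts.get("range2", (0.01, 0.3))))
        kind = opts.get("kind", "hopf")
        mus = np.unique(np.round(np.linalg.eigvalsh(top.laplacian), 9))
        import pandas as pd

        rows = []
        for mu in mus:
            if kind == "branch_point" and mu < 1e-9:
                continue
            c = uniform_mode_curve(params, top, kind, pair, ranges, float(mu),
                                   n_grid=int(opts.get("n_grid", 80)))
            for k2, (v1, v2) in enumerate(c.points):
                rows.append({"mode_mu": mu, pair[0]: v1, pair[1]: v2,
                             "kind": kind,
                             "omega_rad_per_s": (c.omegas[k2] if c.omegas is not None
                                                 and k2 < len(c.omegas) else None)})
        pd.DataFrame(rows).to_csv(outdir / "curve.csv", index=False)
        log.append(f"curve: {len(rows)} points")

    elif config.analysis == "gate":
        from .gates import GateConfig, truth_table

        top = config.array_topology()
        cfg = GateConfig(params=params, topology=top,
                         knockout_sequence=str(opts.get("knockout", "0" * top.N)),
                         **{k: float(v) for k, v in opts.items()
                            if k in ("input_on", "input_off", "knockout_on",
                                     "knockout_off", "pulse_duration")})
        table = truth_table(cfg, infer=bool(opts.get("infer", False)))
        table.to_frame().to_csv(outdir / "truth_table.csv", index=False)
        payload = {"knockout": table.knockout_sequence,
                   "inputs": table.inputs, "outputs": table.outputs,
                   "expressions": [e.text for e in table.expressions]}
        (outdir / "truth_table.json").write_text(json.dumps(payload, indent=1))
        log.append(f"gate: knockout {cfg.knockout_sequence}, "
                   f"resolved={table.resolved}")

    elif config.analysis == "assemblage":
        from . import assemblage as asm
        from .gates import GateConfig

        spec = opts.get("netlist")
        if spec is None:
            raise ValueError("assemblage analysis needs options.netlist")
        comps = []
        for c in spec["components"]:
            kind = c["kind"]
            if kind == "source":
                comps.append(asm.make_source(c["name"], c.get("stream", [])))
            elif kind == "sink":
                comps.append(asm.make_sink(c["name"]))
            elif kind == "tautology_device":
                comps.append(asm.make_tautology_device(params, name=c["name"]))
            elif kind == "memory_pair":
                comps.append(asm.make_memory_pair(params, name=c["name"]))
            elif kind == "gate_array":
                gtop = build_topology(c.get("topology", "cyclic"), int(c.get("N", 3)))
                cfg = GateConfig(params=params, topology=gtop,
                                 knockout_sequence=c["knockout"])
                comps.append(asm.make_gate_array(
                    cfg, c["name"],
                    {p: int(i) for p, i in c.get("inputs", {}).items()},
                    {p: int(i) for p, i in c.get("outputs", {}).items()},
                    {int(k): str(v) for k, v in c.get("fixed", {}).items()}))
            else:
                raise ValueError(f"unknown component kind {kind!r}")
        links = [asm.Link((l["from"][0], l["from"][1]), (l["to"][0], l["to"][1]),
                          delay=float(l.get("delay", 0.0)),
                          blocked=bool(l.get("blocked", False)))
                 for l in spec["links"]]
        net = asm.Netlist(comps, links)
        res = asm.simulate_assemblage(net, opts.get("input_streams", {}),
                                      cycles=int(opts.get("cycles", 4)))
        res.to_frame().to_csv(outdir / "assemblage.csv", index=False)
        log.append(f"assemblage: {len(res.records)} port records"
                   + (f", halted {res.halted}" if res.halted else ""))

    elif config.analysis == "fixtures":
        fixtures = generate_fixtures(config.seed,
                                     n_fixtures=int(opts.get("n_fixtures", 6)))
        (outdir / "fixtures.json").write_text(json.dumps(fixtures, indent=1))
        log.append(f"fixtures: {len(fixtures)}")

    _write_log(outdir, log)
    return outdir


def generate_fixtures(seed: int, n_fixtures: int = 6, max_cells: int = 5) -> list[dict]:
    """Small random connected topologies + parameter draws for property tests.

    Parameters are drawn inside the printed working ranges (sigma_M in
    [60, 150], sigma_inh in [20, 60], k_ADP in [0.02, 0.3], q in
    {1, 1.2, 100}); each fixture records its automorphism group
    (recomputable by brute force) and the uniform stationary state.
    """
    rng = np.random.default_rng(seed)
    fixtures = []
    while len(fixtures) < n_fixtures:
        N = int(rng.integers(2, max_cells + 1))
        delta = np.zeros((N, N))
        # random spanning tree, then optional extra edges
        order = rng.permutation(N)
        for a, b in zip(order, order[1:]):
            delta[a, b] = delta[b, a] = 1.0
        for _ in range(int(rng.integers(0, N))):
            i, j = rng.integers(0, N, 2)
            if i != j:
                delta[i, j] = delta[j, i] = 1.0
        top = ArrayTopology(N=N, delta=delta)
        params = KineticParams(
            sigma_M=float(rng.uniform(60, 150)),
            sigma_inh=float(rng.uniform(20, 60)),
            k_ADP=float(rng.uniform(0.02, 0.3)),
            q=float(rng.choice([1.0, 1.2, 100.0])))
        try:
            xs, ys = uniform_steady_state(params)
        except ValueError:
            continue
        fixtures.append({
            "N": N,
            "delta": delta.tolist(),
            "params": asdict(params),
            "automorphism_group_order": len(automorphisms(top)),
            "uniform_state": {"x": xs, "y": ys},
        })
    return fixtures
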
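# turingcells

Chemical computing with discrete Turing patterns in arrays of mass-coupled
glycolytic cells: a simulator and bifurcation-analysis toolkit.

## The system

Each cell is a continuous stirred tank reactor running the Goldbeter–Moran
skeleton model of glycolysis, with dimensionless ATP (`x`, the inhibitor) and
ADP (`y`, the activator).  `N` cells exchange both species linearly through a
symmetric structural matrix `{δ_ij}` (linear, cyclic, T-shaped or custom
arrays):

    dx_i/dt = f_x(x_i, y_i) + q·k_ADP Σ_j δ_ij (x_j − x_i) + p_i(t)
    dy_i/dt = f_y(x_i, y_i) +   k_ADP Σ_j δ_ij (y_j − y_i)

    f_x = ν + σ_inh y^n/(M^n + y^n) − σ_M x(1+x)(1+y)² / [L + (1+x)²(1+y)²]
    f_y = ϕ σ_M x(1+x)(1+y)² / [L + (1+x)²(1+y)²] − k_s y − ϕ σ_inh y^n/(M^n + y^n)

with ϕ = 1, ν = 1.84 s⁻¹, L = 5·10⁶, n = 4, M = 10, k_s = 0.06 s⁻¹, and four
adjustable parameters: the autocatalysis and inhibition rate coefficients
σ_M, σ_inh and the coupling parameters k_ADP (ADP transport coefficient) and
q (ATP/ADP transport ratio).  The identity ϕ·f_x + f_y = ϕν − k_s·y pins the
uniform stationary ADP level at y\* = ϕν/k_s ≈ 30.67 regardless of σ_M, σ_inh.

In suitable parameter regions, stable *non-uniform* stationary states —
discrete Turing patterns — coexist with stable uniform oscillations.  Pulse
perturbations p_i(t) switch the array between these regimes, which turns an
array into a set of per-cell logic gates: a clocked *central knockout* system
applies input pulses, converts any resulting oscillation back into a
reference pattern, and reads per-cell outputs by thresholding ADP against
y\*.  The package covers the whole pipeline:

- `turingcells.model` — kinetics, topologies and their automorphism groups,
  analytic Jacobian, uniform steady state;
- `turingcells.dynamics` — stiff pulse-driven integration, regime
  classification, period measurement, pattern codes;
- `turingcells.steady_states` — multistart Newton enumeration of stationary
  states with stability and symmetry labels;
- `turingcells.continuation` — pseudo-arclength branch tracing, Hopf / fold /
  symmetry-breaking detection, branch switching, two-parameter bifurcation
  curves, (m, n) region maps, solution diagrams;
- `turingcells.gates`, `turingcells.boolexpr` — the central knockout gate
  machinery and Boolean truth-table verification;
- `turingcells.assemblage` — tautology/contradiction reference device, clock
  + counter, 1-bit memory pairs, and netlist co-simulation;
- `turingcells.workbench`, CLI `turingcells` — config files, result bundles,
  fixture generation.

## Worked example

Three cells in a cyclic array at σ_M = 100 s⁻¹, σ_inh = 35 s⁻¹,
k_ADP = 0.1 s⁻¹, q = 1 sit in a region with 7 stationary states of which 3
are stable Turing patterns (the rotation orbit of "low–high–high"):

```python
from turingcells import KineticParams, build_topology
from turingcells.steady_states import enumerate_states
from turingcells.gates import GateConfig, truth_table

params = KineticParams()                 # the operating point above
top = build_topology("cyclic", 3)
for s in enumerate_states(params, top, seed=0):
    print(s.code, s.symmetry, "stable" if s.stable else "unstable")

cfg = GateConfig(params=params, topology=top, knockout_sequence="011")
table = truth_table(cfg, infer=True)
for word, out in zip(table.inputs, table.outputs):
    print(word, "->", out)
```

prints the state census (the code of the uniform state is not meaningful —
its cells sit exactly at the threshold y\*, so their bits are rounding noise)

```
101 uniform unstable
011 symmetric_nonuniform stable
101 symmetric_nonuniform stable
110 symmetric_nonuniform stable
001 symmetric_nonuniform unstable
010 symmetric_nonuniform unstable
100 symmetric_nonuniform unstable
```

and the simulated truth table of the knockout-{0 1 1} gate

```
011 -> 011
100 -> 011
001 -> 011
010 -> 011
101 -> 101
110 -> 110
000 -> 011
111 -> 011
```

i.e. an input word that is itself a stable pattern (101, 110) installs that
pattern; every other word leaves the array oscillating, and the knockout
pulses then force the reference pattern 011.  Per cell this realizes the
Boolean functions A1·(A2⊕A3), NAND(A1,A3)+A2 and NAND(A1,A2)+A3.

The same census from the shell:

```sh
turingcells states --out results/census --seed 0
turingcells gate --config examples/gate_cyclic3_knockout011.yaml --out results/gate
```

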
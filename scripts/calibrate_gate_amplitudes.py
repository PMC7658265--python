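"""Calibrate the gate input/knockout pulse amplitudes.

Scans (A_on, A_off) candidates and the pulse phase relative to the
oscillation cycle, and reports for each pair the fraction of phases at
which the pulse word (A_off, A_on, A_on) converts uniform oscillations
of the 3-cell cyclic array into the corresponding discrete Turing
pattern (0 1 1).  A usable gate needs installation at every phase,
because the knockout fires at whatever phase the receptor event lands
on.  The packaged defaults (+1.2, -1.0) install at every scanned phase.

Usage: python scripts/calibrate_gate_amplitudes.py [--fine]
"""

import argparse

import numpy as np

from turingcells.dynamics import (
    PerturbationPulse,
    PerturbationSchedule,
    classify_regime,
    pattern_code,
    perturbed_uniform_state,
    simulate,
)
from turingcells.model import KineticParams, build_topology, uniform_steady_state


def installation_fraction(params, topology, a_on, a_off, phases, state, t_ref):
    y_star = uniform_steady_state(params)[1]
    hits = 0
    for off in phases:
        pulses = [PerturbationPulse(2, a_on, t_ref + off, 100.0),
                  PerturbationPulse(3, a_on, t_ref + off, 100.0)]
        if a_off:
            pulses.append(PerturbationPulse(1, a_off, t_ref + off, 100.0))
        traj = simulate(params, topology, state, PerturbationSchedule(pulses),
                        t_end=t_ref + off + 3100.0)
        if (classify_regime(traj) == "turing_pattern"
                and pattern_code(traj.final_state(), y_star) == "011"):
            hits += 1
    return hits / len(phases)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fine", action="store_true",
                    help="2.5 s phase grid instead of 5 s")
    args = ap.parse_args()

    params = KineticParams()
    top = build_topology("cyclic", 3)
    base = simulate(params, top, perturbed_uniform_state(params, top),
                    t_end=2000.0, sample_dt=0.05)
    # phase reference: first receptor-level crossing after 1900 s
    t, y1 = base.times, base.y(1)
    above = y1 > 80.0
    rising = np.where(~above[:-1] & above[1:])[0]
    t_ref = float(t[rising[t[rising] > 1900.0][0]])
    state = base.state_at(t_ref)
    state.t = t_ref
    phases = np.arange(0.0, 50.3, 2.5 if args.fine else 5.0)

    print(f"phase reference t = {t_ref:.1f} s; {len(phases)} phases")
    print(f"{'A_on':>6} {'A_off':>6} {'install fraction':>18}")
    for a_on in (1.0, 1.2, 1.5, 2.0, 3.0):
        for a_off in (0.0, -0.5, -1.0, -2.0):
            frac = installation_fraction(params, top, a_on, a_off,
                                         phases, state, t_ref)
            marker = "  <-- phase-robust" if frac == 1.0 else ""
            print(f"{a_on:6.1f} {a_off:6.1f} {frac:18.2f}{marker}")


if __name__ == "__main__":
    main()
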
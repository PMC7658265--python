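# Methods

## Model

Each cell runs the two-variable Goldbeter–Moran core of glycolysis
(dimensionless ATP `x` as inhibitor, ADP `y` as activator): allosteric
autocatalysis of phosphofructokinase with rate coefficient σ_M and allosteric
constant L, Hill-type product inhibition with coefficient σ_inh, Michaelis
constant M and Hill exponent n, constant ATP uptake ν, linear ADP removal
k_s, and the dissociation-constant ratio ϕ.  Fixed values: ϕ = 1,
ν = 1.84 s⁻¹, L = 5·10⁶, n = 4, M = 10, k_s = 0.06 s⁻¹.  Cells are coupled by
linear mass exchange: ADP with transport coefficient k_ADP, ATP with q·k_ADP,
through a symmetric zero-diagonal structural matrix {δ_ij}.  Built-in
topologies: linear chain, cycle, and the T-shaped 4-array with cell 2 as hub
(chosen so the hub is the cell that stays locked at logic 1 in the T-shaped
gate configurations; arbitrary matrices are accepted for anything else).
ATP pulse perturbations p_i(t) are piecewise constant (cell, amplitude,
start, duration).

Two exact structural facts anchor many tests: (i) ϕ·f_x + f_y = ϕν − k_s·y,
so the uniform stationary ADP level is y\* = ϕν/k_s independent of σ_M and
σ_inh, and the uniform ATP level x\* is the unique root of f_x(x, y\*) = 0;
(ii) at any uniform state the 2N×2N Jacobian block-diagonalizes over the
eigenvalues μ of the graph Laplacian into 2×2 blocks
A(μ) = J_cell − μ·diag(q·k_ADP, k_ADP), so every uniform-state bifurcation is
a scalar condition on one spatial mode: Hopf at tr A(μ) = 0 with det A(μ) > 0
(frequency ω = √det A), symmetry breaking at det A(μ) = 0 for μ > 0.

## Numerics

*Integration.* LSODA (via `scipy.integrate.odeint`) driving a
numba-compiled right-hand side and analytic Jacobian, rtol 1e-8 / atol
1e-10, restarted at every pulse boundary so the discontinuities of p_i(t)
are exact.  Dense sampling (default 0.25 s) feeds peak detection;
sampled maxima are refined by local quadratic interpolation.
Concentrations are checked non-negative after every segment (tolerance
−10⁻⁶, tiny undershoots floored at 0).

*Regimes.* A trajectory tail (window 2000 s after the last pulse) is
stationary when every component's peak-to-peak excursion is below 10⁻³
(absolute) and uniform when the maximal inter-cell ADP deviation is below
10⁻³ relative; a stationary non-uniform tail is a discrete Turing pattern.
Both tolerances are configurable; the source text never defines "settled",
and these values sit three orders below the pattern contrast (~38 ADP
units) and above integrator noise.

*Periods.* Fast mode: mean spacing of large-amplitude ADP maxima (above the
receptor level 80, which separates the ~87-peak spikes from small ripples).
Slow mode: the sequence of per-cycle maxima is treated as the envelope and
the mean spacing of its own (interpolated) maxima is returned.

*Stationary states.* Damped Newton on the analytic Jacobian, residual
‖rhs‖∞ < 10⁻¹⁰, negative-concentration roots discarded.  Enumeration is
multistart Newton (vectorized over starts) from a scrambled Sobol sample of
the per-cell box [0, 5x\*]×[0, 5y\*] — oscillation maxima stay below
≈ 2.6·y\*, so the box covers observed ranges — plus the uniform state and
optional warm starts; results are closed under the automorphism group
(brute-force permutation search; arrays are small) and deduplicated in the
scaled max-norm at 10⁻⁶.  Enumeration is heuristic: counts must stabilize
under more starts (asserted at the operating point) and are cross-checked
against continuation branches.

*Continuation.* Pseudo-arclength predictor–corrector with the parameter
scaled by its window width and the state by its magnitude; initial step
10⁻², bounds [10⁻⁶, 0.05]; tangent from the bordered system, full Newton
corrector, step halving on failure and growth on fast convergence; closed
loops detected by return to the start point.  Stability is recomputed at
every point (2N ≤ 8, dense eigensolves are cheap — chosen over bialternate
test functions).  Uniform branches use the exact mode reduction for
bifurcation detection (brentq on tr A / det A per mode, which also handles
the degenerate double modes of cyclic arrays); general branches pair
eigenvalues of consecutive points by nearest matching and bisect the
crossing with the corrector re-solving intermediate states.  Fold vs branch
point at a real-eigenvalue crossing: parameter-critical tangent (|t_p| <
10⁻³ scaled) means fold.  Branch switching perturbs along the null
eigenvector on both sides (parameter nudged off the singular value) and
corrects at fixed parameter.

*Two-parameter curves.* Uniform-state curves are the mode-reduction
conditions continued directly (grid in the second parameter, brentq in the
first); a Hopf curve ends where det A → 0 (Bogdanov–Takens, ω → 0), and
intersections of two mode curves mark double-Hopf candidates.  Bifurcations
of non-uniform states have no reduction and are continued sequentially:
the state is tracked by warm-started Newton in the second parameter while
the stability boundary is re-localized in the first by bisection on the
leading eigenvalue.  This sequential scheme replaces arclength continuation
of the full bordered system; for the curves of interest (secondary Hopf
boundaries transverse to the swept parameter) it is equally accurate and
considerably more robust near the orbit-connecting folds.

## Gate protocol

Clock ticks at t_k = 1000·k + 600 s.  Input word pulses (duration 100 s)
start 100 s before a tick: bit 1 → +1.2, bit 0 → −1.0.  From the tick
onward each cell's receptor watches for ADP exceeding 80 (the signature of
large-amplitude oscillation; patterned cells stay below ~66); at the first
receptor event the knockout pulses fire (same amplitudes, keyed by the
knockout word), and outputs are read 900 s after the tick as the ADP
pattern code against y\*.  An output is flagged unresolved if the final
100 s window still moves by more than 1 ADP unit.  Truth tables chain one
cycle per input word, starting from developed uniform oscillation.

The pulse amplitudes are calibrated (`scripts/calibrate_gate_amplitudes.py`):
the (+2.0, −1.0) pair that installs patterns in linear arrays never converts
oscillation into a pattern in the 3-cell cyclic array at any pulse phase,
while (+1.2, −1.0) does so at every phase — essential, because the knockout
fires at whatever phase the receptor event happens to land on.  With these
amplitudes the three 3-cell knockout gates and the four-cell configurations
reproduce their printed per-cell Boolean functions bit-for-bit, and outputs
are invariant to ±10 s clock jitter and to integrator-tolerance halving.

## Assemblage idealizations

Channels between components are delayed binary links: the excitable-channel
chemistry that would carry the signals is abstracted away, and no mass
flows between components.  Co-simulation is lock-step per 1000 s clock
interval: reference devices, sources and memories publish bits, each gate
array runs one full ODE gate cycle on its wired input word, sinks and
memory writes consume the results.  Counter and knockout switches are ideal
digital elements.  The tautology/contradiction device is two cells locked
into (1, 0) by the long-pulse protocol; a memory pair stores one bit as the
(1, 0)/(0, 1) pattern, written by a simultaneous ±pulse pair and read
without disturbance.

## Study conditions and problem sizes

All chemical-computing results use the operating point σ_M = 100 s⁻¹,
σ_inh = 35 s⁻¹, k_ADP = 0.1 s⁻¹, q = 1 (3 stable Turing patterns in the
3-cell cycle, 4 in the 4-cell cycle, 2 in the 4-cell chain).  The
acceptance protocols use: 5000 s single-cell runs (2000 s transient
discarded) for the period; a 0.1-amplitude-step scan plus edge bisection to
0.01 for the robustness bounds; a 25 s-step delay scan to 1000 s for
two-pulse induction; a σ_inh grid of step 1 on [20, 60] with σ_M bisection
to 10⁻³ for the secondary Hopf curve; a (σ_M, σ_inh) grid of 2.5 × 1 with
512-start enumeration per node (warm-started along columns) for the
five-pattern onset; and 120 k_ADP columns on [5·10⁻⁴, 0.05] for the q = 100
symmetry-breaking curve.  These sizes put every grid-resolution error well
below the tolerances quoted for the corresponding quantities.

## Known limitations and negative findings

- **No ~400 s envelope modulation.**  The two-cell array at the operating
  point has exactly two attractors — the uniform limit cycle (period
  50.2919 s) and the Turing pattern.  The uniform cycle synchronizes
  in-phase within about one cycle from any tested initial condition
  (near-uniform, strongly asymmetric, anti-phase, cold start; k_ADP from
  0.005 to 0.2; also 3-cell arrays), and its envelope of maxima is flat to
  below 10⁻⁴.  Apparent envelope periods measured on sampled trajectories
  (e.g. ~302 s at a 0.25 s sampling step, ~604 s at 0.1 s) are moiré
  between the oscillation period and the sample grid, not dynamics.  The
  slow-envelope protocol is implemented and reported as defined, but its
  output at these conditions measures residual sampling ripple; no
  parameter choice we examined produces a genuine ~400 s small-amplitude
  mode in these arrays.
- **Pattern robustness is non-monotone.**  The installed two-cell pattern
  survives positive 100 s pulses up to ≈ 0.35 and again between ≈ 0.95 and
  ≈ 1.45, but switches to oscillation in the intermediate window
  (0.4–0.9).  The robustness bound reported is the outermost surviving
  amplitude; blanket statements of the form "resistant to all A ≤ 1.2" do
  not hold in this implementation.
- **Two-pulse induction is phase-dominated.**  Single 100 s pulses of
  amplitude 1.2 already install the pattern at roughly 45% of oscillation
  phases, and a preceding pulse neither widens nor narrows the installing
  phase window of a second pulse (matched controls).  The largest
  pattern-inducing delay in a two-pulse scan is therefore governed by where
  the second pulse lands in the cycle, not by a decaying memory of the
  first pulse.
- Enumeration carries no global completeness guarantee; region labels are
  validated against branch-collected states (agreement asserted at ≥ 95% of
  nodes) but can in principle under-count elsewhere.
- Periodic orbits are not continued; oscillatory regimes are characterized
  by direct simulation only, and sub/supercritical Hopf labels are inferred
  from nearby branch behaviour rather than normal forms.
- The assemblage layer is a signal-level idealization; it does not model
  the reaction–diffusion channels, their propagation failures, or mass
  leakage between coupled blocks, so its results speak to the logic design,
  not to channel chemistry.
- The synthetic fixture generator draws random connected arrays (N ≤ 5) and
  parameters inside the working ranges; it emulates array diversity for
  property tests (equivariance, closed-form uniform states), not realistic
  experimental noise — passing those tests says nothing about measurement
  error or parameter drift in a wet system.
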
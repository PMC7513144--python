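# Methods

## The model

`szcascade` treats a signal-transduction chain as an ordered series of
activation/inactivation cycles. Step `j` holds a signalling species with a
conserved total `X_j^0 = X_j + X_j*`; the active form of step `j` catalyses
activation of step `j+1` with mass-action rate `v_j = k_j A X_j* X_{j+1}`
(mediator/ATP concentration `A`), and a phosphatase reverts it with
`v_-j = k_-j Ph_{j+1} X_{j+1}*`. The receptor (step 1) is driven by a
ligand, `k_on L X_1` against `k_off X_1*`, which keeps every cycle in one
uniform shape. The terminal step may carry an irreversible
pseudo-first-order drain (`k_out`, default 0) standing in for transcription;
its product is tracked only as a cumulative counter since no rate law beyond
first order is assumed.

Assumptions: well-mixed compartments (no diffusion), no cooperativity or
ultrasensitivity, no explicit ADP/Pi pools, mediator held by a chemostat
unless a finite-ATP mode is requested, and signalling much faster than
protein synthesis (totals constant).

Steady states follow the closed-form partition
`X_{j+1}^st* = a/(a+b) X_{j+1}^0` with `a = k_j p(j+1|j) A X_j^st*`,
`b = k_-j p(j|j+1) Ph_{j+1}`. Two deliberate choices here:

* The same total `X_{j+1}^0` normalises both the active and the inactive
  partition, so conservation holds exactly (the alternative — a different
  total in the active branch — breaks it).
* The transition probabilities `p(j+1|j)`, `p(j|j+1)` weighting the balance
  have no canonical steady-state values in this model; they default to 1
  (pure rate balance) and are free per-step parameters. Detailed balance
  `p(j|j+1) v_-j = p(j+1|j) v_j` then holds at the constructed steady state
  to floating-point rounding regardless of their values.

## Information-theoretic layer

The binary code counts arrangements exactly with log-gamma
(`log Ψ = logΓ(X+1) − Σ logΓ(X_j+1) − Σ logΓ(X_j*+1)`); counts must be
integers (Omega-scaled concentrations rounded), otherwise the arrangement
count is undefined and the report records NaN. The Shannon form
`S = −X Σ (p log p + p* log p*)` uses `0 log 0 = 0`. The relative gap
between the two is the Stirling error; it falls below 0.1% by pools of 1e5
molecules.

`log(p/p*)` with a zero probability raises an explicit error with guidance
to regularise, never a silent infinity.

Within one step the two symbols can be normalised in two ways: by the global
pool (`p_j + p_j*` equals the step's share of `X`) or strictly per step
(`p + p* = 1`), the latter bridging to the channel layer. Both are exposed;
the entropy-difference and current formulas only ever use the ratio, which
the choice does not affect.

The step channel: noise probability `φ` enters only through its binary
entropy `ξ(φ)`. One symbol overloading had to be resolved: `exp(ξ)` (range
[1, 2]) cannot itself be a probability, so it is stored as a distinct
capacity parameter `Phi` and never conflated with `φ`. Similarly "entropy
current" `C_j` (information layer) and "channel capacity" `C_j` (channel
layer) are distinct named fields in distinct modules. The conditional-entropy
term at the optimum is evaluated as `ξ q* = ξ/(Φ+1)`, which reproduces the
closed form `C_fwd = −log(Φ/(Φ+1))`; the reverse channel puts the penalty on
the complementary symbol (`+ξq`), shares the optimal input, and gives
`C_rev = log(Φ+1)`. A uniform-grid brute-force maximiser of both objectives
is kept in the public API as the independent check of the Lagrange algebra.
Inverting `ξ = log(p/p*)` returns the branch `φ ∈ (0, 0.5]`; the mirror
branch is available by flag, and ratios outside `[0, ln 2]` have no solution
and say so.

## Simulation

* ODE path: LSODA via `scipy.integrate.solve_ivp`, rtol 1e-8, atol 1e-11.
  Ligand pulses are integrated piecewise at the discontinuity. Active
  concentrations are clipped to `[0, X_j^0]` after integration; inactive
  forms are reconstructed from the conservation law, so conservation is
  exact by construction.
* Stochastic path: Gillespie's direct method on counts
  `round(Ω · concentration)`, propensities Ω-scaled from the mass-action
  rates; one seeded `numpy` generator per run, replicate `r` seeded
  `base + r`. Conservation is exact (integer bookkeeping). Every firing is
  logged as `(time, step, direction)`.
* Cycle timing: on a trajectory, the activation duration `τ_j` is the time
  for the active excess over the initial baseline to first reach 95% of its
  peak, and the recovery duration `τ_-j` (stored negative) runs from that
  crossing until the excess first falls below 5% of peak. The thresholds
  are explicit parameters because a continuous trace has no unique "end of
  rise"; first crossings are resolved at the earliest grid time. Scaling
  all rates by `c` scales both durations by `1/c` (tested). Note that with
  this onset-anchored definition a symmetric pulse read at equal 50%
  thresholds does *not* give equal magnitudes — the recovery clock starts at
  the rise crossing, not at the peak.

## Synthetic pulse generator and the AEPR study conditions

Measured phosphorylation time courses show a stereotyped shape: a fast rise
to peak and a much slower relaxation back to baseline. The generator
reproduces it as a per-step double exponential
`a (e^{−g t} − e^{−r t})`, normalised to a chosen peak amplitude, with rise
rate `r` and recovery rate `g`. Defaults (five steps, `r ≈ 8–12`,
`g ≈ 0.045–0.06` in inverse time units, amplitude 0.8 of a unit total) put
the extracted durations in the strongly separated regime
`τ_j/|τ_-j| ≈ 0.01`, which is what the entropy-coding limit assumes.

This separation is a *postulate about real cascades*, not a consequence of
the mass-action model: in a single cycle the resting activity and the
recovery rate are controlled by the same parameter (`k_-j Ph`), so a chain
with bounded resting active fractions cannot make recovery arbitrarily slow
relative to activation. The mechanistic preset below reaches
`τ_j/|τ_-j| ≈ 0.05–0.07` — comfortably `τ_j < |τ_-j|`, but not the extreme
regime. The AEPR analyses therefore run on generator pulses, where the
regime is imposed as a study condition.

The AEPR pipeline: generate pulses → extract `τ_j, τ_-j` → entropy-code
`p_j = e^{−βτ_j}`, `p_j* = e^{βτ_-j}` from a single β (default 0.01 inverse
time, chosen so `β|τ_-j| ≈ 0.6` keeps both probabilities well inside (0,1))
→ draw transition counts → estimate `ζ_j = log(n_fwd/n_rev)/(τ_j − τ_-j)`
per replicate. Transitional probabilities are identified with the
per-step-normalised selection probabilities — the identification detailed
balance licenses — and the measurement ensemble is binomial: each of Ω=1000
molecules per step completes its cycle forward with probability
`p/(p+p*)`, 500 replicate cycles. The estimator's finite-duration bias is
`(|τ_-j|−τ_j)/(|τ_-j|+τ_j) ≈ 1−2τ_j/|τ_-j|`, about 2% under the defaults.
Sign convention: the forward-direction AEPR is `−β`, the reverse `+β`; the
raw log-ratio estimator returns the positive magnitude and the report
assigns the signs.

What passing this recovery does and does not show: it validates the
estimator chain (timing extraction, coding, counting, aggregation) under
idealised pulse shapes, binomial measurement noise, and an exactly shared β.
Real trajectories add kinetic noise, step-dependent shapes, baseline drift
and estimator model error, none of which the generator emulates; a CV below
5% here is a correctness check, not evidence about any real pathway.

## Entropy production

Two routes are implemented:

* Concentration route, per step:
  `σ_j = −log[(1 + ΔX_{j+1}/X^st) / (1 + ΔX_{j+1}*/X^st*)]`, returned
  dimensionless (an optional kBT factor converts to energy units — the
  timing-based form `σ_j = |ζ|(τ_j − τ_-j)` is dimensionless, and internal
  consistency wins over decorating one formula with kBT).
* ATP-ledger route: `σ = −Σ log(A_jf/A_ji)`, with the linearised `Σ ΔA_j/A`
  reported alongside; a sequential ledger telescopes.

`atp_route_consistency` compares them on a single cycle held quasi-static
while the mediator is drained (default 1.5% of `A0` over ~60 relaxation
times): both routes then measure the same depletion event and agree in
magnitude to ~2%. The comparison is on magnitudes because the two printed
sign conventions disagree for the same event (the active form falls while
ATP is consumed, making the concentration-route sign negative and the
ledger-route sign positive); the magnitude is the physically comparable
quantity in the linear regime. The kinetic prefactor
`log(k_j A X_j*/(k_-j Ph_{j+1}))` that the linearised theory drops is
computed as a user-facing diagnostic rather than silently neglected.

## Built-in preset

The five-step growth-factor preset (EGFR, Ras, c-Raf, MEK, ERK) lives in a
versioned data file, not code. All of its numbers are package defaults in
arbitrary units — not measured constants — chosen once so that (i) the
resting (sustained-ligand) steady state keeps every active fraction in
(0, 0.5], which the binary code needs for `log(p/p*) ≥ 0`, and (ii) a ligand
pulse (L = 5 until t = 0.5, from rest) relays a transient down all five
steps with `τ_j < |τ_-j|` everywhere. Values: totals 1, `k_fwd` 10, `k_rev`
1, `Ph = (1, 2, 4, 6, 8)` (increasing phosphatase keeps downstream resting
fractions bounded against the chain's gain), `A0 = 1`, resting ligand 0.02,
`k_on = 1`, `k_off = 0.5`, Ω = 1000.

## Problem sizes

Default analysis sizes, chosen to keep every check cheap while leaving the
estimators' errors an order of magnitude inside their tolerances: channel
oracle grid 1e5 points over 50 random noise levels; Stirling check up to
1e5 molecules; 100 random cascades for the balance residual; AEPR ensemble
500 replicates × 5 steps × 1000 molecules; stochastic-vs-ODE convergence 60
replicates at Ω = 1000 on a clamped cycle.

## Known limitations

* No spatial structure, delays, Hill kinetics, or far-from-steady-state
  corrections; the fluctuation-theorem estimator assumes proximity to
  detailed balance.
* The finite-duration AEPR estimate approximates an infinite-time limit
  with one cycle duration; bias shrinks with timescale separation but never
  vanishes.
* All steps evolve concurrently; a strictly sequential (compartment-gated)
  relay is not modelled.
* The stochastic simulator is a plain direct-method loop; very stiff or
  very large-Ω systems will be slow (no tau-leaping).
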
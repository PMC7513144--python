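# szcascade

Information thermodynamics of signal-transduction cascades.

Cell signalling relays a stimulus down an ordered chain of
activation/inactivation cycles — the growth-factor MAPK pathway
(EGFR → Ras → c-Raf → MEK → ERK) being the canonical example. Each step `j`
holds a signalling protein in an inactive form `X_j` or an active
(phosphorylated) form `X_j*`, so the cascade is a binary code over molecule
states. `szcascade` gives quantitative biologists and modellers a toolkit to
ask thermodynamic questions about such a chain: how much information does one
step transmit, how much chemical work can a cycle extract from that
information, and how fast is entropy produced while the signal runs.

## Model

For totals `X_j + X_j* = X_j^0` with selection probabilities `p_j = X_j/X`,
`p_j* = X_j*/X`, the package computes (natural logs throughout):

* **Code entropy.** The number of distinguishable molecule arrangements
  `Ψ = X!/∏ X_j! X_j*!` (exact, via log-gamma) and its Stirling limit, the
  Shannon entropy `S = −X Σ (p_j log p_j + p_j* log p_j*)`. A signalling
  fluctuation `ΔX_j*` carries the entropy difference
  `H_j = ΔX_j* log(p_j/p_j*)`, with per-molecule density
  `h_j = log(p_j/p_j*)`.
* **Channel capacity.** Each step is a two-symbol noisy channel with noise
  probability `φ` and noise entropy `ξ = −φ log φ − (1−φ) log(1−φ)`. With
  `Φ = exp(ξ)` the optimal input is `q = Φ/(Φ+1)`, and
  `C_fwd = −log(Φ/(Φ+1))`, `C_rev = log(Φ+1)`, so that
  `h = C_rev − C_fwd = ξ = log(q/q*)`. A brute-force grid maximiser verifies
  the closed forms.
* **Szilard-engine work.** Treating each cycle as a feedback-controlled
  engine, the chemical work is `w_j = k_B T · h_j · ΔX_j*`; a single molecule
  at 2:1 odds yields the classic `k_B T ln 2`.
* **Entropy coding and AEPR.** The code probabilities can be tied to the
  cycle durations via one cascade-wide average entropy production rate
  (AEPR) β: `−log p_j = β τ_j`, `log p_j* = β τ_−j` (activation duration
  `τ_j > 0`, recovery `τ_−j < 0`). The fluctuation theorem turns empirical
  forward/backward transition frequencies into per-step AEPR estimates
  `ζ_j ≈ log(n_fwd/n_rev)/(τ_j − τ_−j)`, whose step-to-step dispersion tests
  the single-rate hypothesis.
* **Kinetics.** Mass-action rate laws `v_j = k_j A X_j* X_{j+1}` (ATP
  mediator `A`) and `v_−j = k_−j Ph_{j+1} X_{j+1}*` (phosphatase), closed-form
  steady states satisfying detailed balance, a deterministic ODE integrator,
  an exact Gillespie simulator, and a finite-ATP mode whose depletion ledger
  gives the entropy production a second, independent way:
  `σ = −Σ log(A_f/A_i) ≈ Σ ΔA/A`.

## Worked example

The capacity of a maximally noisy step (`φ = 0.5`):

```bash
$ szcascade capacity --phi 0.5
{
  "C_fwd": 0.40546510810816444,
  "C_rev": 1.0986122886681098,
  "Phi": 2.0,
  "h_step": 0.6931471805599454,
  ...
}
```

`C_fwd = ln(3/2)`, `C_rev = ln 3`, and the step mutual entropy
`h = C_rev − C_fwd = ln 2`: at the noise maximum one cycle transmits exactly
one bit, the same bit whose Szilard conversion is worth `k_B T ln 2` of work.

AEPR consistency on an entropy-coded cascade (five stereotyped pulses, one
shared β = 0.01; 500 replicate cycles of 1000 molecules per step):

```bash
$ szcascade aepr --beta 0.01 --replicates 500 --seed 1
{
  "beta_hat": 0.009930054311287784,
  "beta_true": 0.01,
  "cv_across_steps": 0.005213679388603212,
  "relative_error": 0.006994568871221581,
  "zeta_fwd": -0.009930054311287784,
  "zeta_rev": 0.009930054311287784,
  ...
}
```

The per-step estimates agree to 0.5% across steps and recover β within 0.7%:
when the code is driven by one production rate, the estimated AEPR is indeed
constant along the cascade (forward estimates carry the negative sign,
recovery the positive one).

Simulating the built-in five-step growth-factor preset and writing tidy
tables:

```bash
szcascade simulate --preset mapk --mode ode --t-max 40 --out out/
szcascade simulate --preset mapk --mode ssa --t-max 5 --seed 2 --out out/
szcascade thermo            # pulse timing + per-step Szilard work
```

`thermo` reports, per step, the activation/recovery durations
(`τ_fwd ≈ 0.4–0.7`, `τ_rev ≈ −6…−12` for the preset: activation is an order
of magnitude faster than recovery) and the work `k_B T h_j ΔX_j*` each cycle
could extract from its pulse.

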
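# Built-in 5-step growth-factor cascade preset (EGFR -> Ras -> c-Raf -> MEK -> ERK).
#
# All numbers are package defaults in arbitrary concentration/time units,
# chosen so that (i) a ligand pulse relays a fast-rising, slower-recovering
# transient down every step (activation duration shorter than recovery
# duration), and (ii) the sustained-ligand steady state keeps each step's
# active fraction within (0, 0.5].  They are not measured rate constants.
cascade:
  step_names: [EGFR, Ras, c-Raf, MEK, ERK]
  X0: [1.0, 1.0, 1.0, 1.0, 1.0]
  k_fwd: [10.0, 10.0, 10.0, 10.0]
  k_rev: [1.0, 1.0, 1.0, 1.0]
  Ph: [1.0, 2.0, 4.0, 6.0, 8.0]
  A0: 1.0
  temperature_kBT: 1.0
  volume_scale: 1000.0
  ligand: 0.02
  k_on: 1.0
  k_off: 0.5
  k_out: 0.0
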
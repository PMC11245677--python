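# Default analysis configuration: the published study setup.
# Override any block and pass the file to `segclock run-all --config`.
seed: 1

species:
  xenopus_laevis:
    name: "Xenopus laevis"
    gene:
      name: "hes5.7L"
      primary_length: 1604
      coding_length: 465
      intron_lengths: [166, 113]
    nuclear_radius_um: 4.0
    clock_period_min: 56.0
    # Tabulated mRNA export delays (minutes), fixed inputs to the DDE stage;
    # the pipeline reports freshly simulated estimates alongside.
    export_delay_min: {normal: 6.39, fractional: 8.36}
  ambystoma_mexicanum:
    name: "Ambystoma mexicanum"
    gene:
      name: "hes7"
      primary_length: 8272
      coding_length: 783
      intron_lengths: [3017, 1260, 2030]
    nuclear_radius_um: 5.5
    clock_period_min: 154.0
    export_delay_min: {normal: 11.97, fractional: 26.27}

kinetics:
  a: 4.5                 # protein/mRNA/min
  k: 33.0                # mRNA/min/cell
  h_m: 3.0               # mRNA half-life, min
  h_p: 15.0              # protein half-life used by the sensitivity baseline, min
  n: 2                   # Hill coefficient (repressor dimers)
  critical_concentration_molar: 1.0e-9

rates:
  transcription_nt_per_s: 20.0
  translation_nt_per_s: 6.0
  splicing_fraction: 0.083

grid:
  delay_halfwidth_min: 5.0
  delay_step_min: 0.5
  h_p_min: 3.0
  h_p_max: 22.0
  h_p_step: 1.0
  t_span_min: 3100.0
  dde_step_min: 0.02
  capture_tolerance_min: 2.0
  min_amplitude_molecules: 10.0

export:
  n_trajectories: 10000
  hurst: 0.25
  reference_radius_um: 3.0
  reference_time_min: 3.36
  radii_um: [3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0]
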
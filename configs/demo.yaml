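# End-to-end demo: generate synthetic inputs, analyse them, and compare a
# sulfane-sulfur pulse against the baseline circuit.
# Run:  adpa-circuit run --config configs/demo.yaml --out-dir results/demo
seed: 42
stages:
  stability:
    params: {}
  generate:
    fp:
      Kd_true: 50.0      # nM
      noise_scale: 0.005
    qpcr:
      true_fold: 30.0
      ct_noise_sd: 0.2
    peptides:
      persulfidated_positions: [62]
      ratio_percent: 17.0
  pulse_compare:
    schedule:
      events:
        - {time: 300.0, amount: 2000.0}   # nM sulfane-sulfur equivalents
    integration: {horizon: 1500.0, dt: 1.0}
  fit_kd: {}
  qpcr: {}
  digest_match:
    tol_ppm: 10.0
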
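# Example analysis configuration: small synthetic demo trial.
out_dir: demo_out
scenarios: [base, on_top, optimal]
endpoints: [phq9, qaly]
n_reps: 500
seed: 7
design: {n_intervention: 20, n_control: 16, n_sites: 2}
sim_params: {dropout_prob_per_occasion: 0.1}
lam_grids:
  phq9: [0, 2000, 100]
  qaly: [0, 100000, 5000]
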
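# Demo configuration for `riboscape all --config examples/demo.yaml`
# A reduced version of the default 2000-gene study design.
n_genes: 500
seed: 2
n_reps_per_group: 3
dispersion: 0.1
baseline_mean: 500.0
effect_log2fc: 2.0
uorf_plant_rate: 0.3
lfc_thr: 1.0
fdr_thr: 0.05
max_fold_len: 300
fold_sample_per_bin: 50
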
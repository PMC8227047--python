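# Demo analysis: 8 subjects x 2 sampling schemes x 2 parcellation scales.
# Small enough to run on a laptop in minutes; m is reduced from the
# standard 1000 nulls to 200 (both documented in docs/methods.md).
out_dir: results/demo
seed: 17
threshold: 0.001
consensus: 0.75
m: 200
alpha: 0.05
rich_fraction: 0.20
simulate:
  base:
    model: planted_richclub
    hub_fraction: 0.20
    p_rr: 0.9
    p_rf: 0.3
    p_ll: 0.1
  n_subjects: 8
  edge_noise: 0.05
  weight_mean: 50.0
  weight_dispersion: 0.5
  schemes:
    - tag: b1000
      long_range_p: 0.0
    - tag: b1000_3000_5000_10000
      long_range_p: 0.01
  scales: [68, 120]
  seed: 17
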
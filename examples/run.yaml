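# Full synthetic demo: generate inputs, then run every analysis stage.
seed: 1
outdir: demo_run
stages: [simulate, repeats, annotate, targets, cohort, survival, motility]
simulate:
  planted_runs:
    - [GGAA, 1, 10]
    - [GGAA, 3, 8]
    - [GGAA, 5, 6]
    - [TTCC, 2, 8]
  n_peaks: 40
  n_genes: 100
  n_tracks: 8
repeats:
  window: 500
annotate:
  flank: 5000
  mark_window: 10000
targets:
  fc: 1.5
  fdr: 0.05
cohort:
  method: pearson
  q_cut: 0.01
  p_cut: 0.01
  regulator: reg_0000
survival:
  split: median
motility:
  min_quality: 100.0
  min_occurrences: 10
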
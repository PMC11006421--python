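# Desk-scale end-to-end demo: simulate all inputs with the default
# study-condition parameters, then run every analysis arm.
#   flniche run --config configs/demo.yaml --seed 1 --out demo_run
seed: 1
outdir: demo_run
spatial:
  n_permutations: 500
clustering:
  k: 15
  margin: 0.0
flow:
  grid: [10, 10]
  K: 3
  resamples: 100
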
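# Full-pipeline configuration: simulate -> build-cohort -> fit -> evaluate
# -> compare. Any SimConfig field may appear under `sim`.
seed: 1
sim:
  n_persons: 20000
  n_codes: 2000
  n_main_items: 300
cohort:
  validation_share: 0.10
  deflators:
    2018: 1.0
evaluate:
  percentile_edges: [50, 75, 90, 95, 99]
  frequency_residuals: true
models:
  - name: age_sex
    systems: []
  - name: hcc
    systems: [hcc_like]
  - name: ccsr
    systems: [ccsr_like]
  - name: dxi
    systems: [ccsr_like, dxi]
  - name: dxi_stepwise
    systems: [ccsr_like, dxi]
    stepwise: true
    entry_p: 1.0e-4
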
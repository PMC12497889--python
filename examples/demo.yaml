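seed: 1
output_dir: runs/demo
simulate:
  lakes:
  - name: GRD
    regime: gradient
    trophic: mesotrophic
  - name: STB
    regime: stable
    trophic: oligotrophic
  start_month: 2021-05
  n_months: 8
  depths: 2
  fractions:
  - PA
  - FL
  n_taxa: 120
  community_size: 4000
  turnover: 0.3
ncm:
  n_bootstrap: 300
nullmodels:
  n_null: 199
  group_by:
  - lake
  - fraction
stability:
  method: braycurtis
  group_by:
  - lake
  - fraction
plspm:
  n_bootstrap: 199
  alpha: 0.1
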
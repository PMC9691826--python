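# Default epithelial tubo-ovarian cancer model configuration.
# See config_bc.yaml for provenance notes; "synthetic" blocks are placeholders
# generated by pedrisk.fixtures, not published values.
schema: 1
model: eoc
primary: eoc
cancers: [eoc, bc, mbc, pancreas]
genes_file: genes.tsv
rr_file: rr.tsv
pathology: synthetic
polygene:
  sd: 1.1          # constant sigma_P(t); synthetic placeholder value
  n_levels: 7
  prs_alpha2: 0.05 # fraction of polygenic variance explained by the PRS
risk_categories:
  bc:
    thresholds: [0.17, 0.30]
    labels: [near-population, moderate, high]
  eoc:
    thresholds: [0.05, 0.10]
    labels: [near-population, moderate, high]
risk_factors:
  - name: height
    type: continuous
    mean: 162.81
    sd: 6.452
    log_rr_per_sd: 0.10130
    n_bins: 5
  - name: qrf       # reproductive/hormonal risk factors, synthetic joint summary
    type: categorical
    masses: [0.3, 0.5, 0.2]
    rrs: [0.8, 1.0, 1.3]
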
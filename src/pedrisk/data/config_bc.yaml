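# Default breast-cancer model configuration.
# Gene parameters (allele frequencies, screening sensitivities, age-piecewise
# relative risks) are the published point estimates shipped in genes.tsv/rr.tsv.
# The polygenic SD and the pathology/risk-factor distributions marked
# "synthetic" are placeholders generated by pedrisk.fixtures, NOT published
# values; do not use them for clinical prediction.
schema: 1
model: bc
primary: bc
cancers: [bc, eoc, mbc, prostate, pancreas]
genes_file: genes.tsv
rr_file: rr.tsv
pathology: synthetic
polygene:
  sd: 1.2          # constant sigma_P(t); synthetic placeholder value
  n_levels: 7
  prs_alpha2: 0.20 # fraction of polygenic variance explained by the PRS
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
  - name: qrf       # questionnaire-based risk factors, synthetic joint summary
    type: categorical
    masses: [0.25, 0.50, 0.25]
    rrs: [0.75, 1.0, 1.4]
  - name: md        # mammographic density (BI-RADS-like), synthetic
    type: categorical
    masses: [0.10, 0.40, 0.40, 0.10]
    rrs: [0.6, 0.9, 1.2, 1.9]
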
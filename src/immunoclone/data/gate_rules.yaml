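# Default B-cell gating rulebook. Features are computed per cluster:
#   percBCR_high     fraction of droplets above the 95th percentile BCR nUMIs
#   PC_score         plasma-cell signature module score (cluster mean)
#   pct_unmutated    fraction of cells with 0 SHM
#   pct_IGHDM        fraction of cells with IGHD or IGHM isotype
#   mean_CD27        mean CD27 expression
rules:
  - label: plasma cell
    priority: 1
    predicates:
      - {feature: percBCR_high, comparator: ">", threshold: 0.4}
      - {feature: PC_score, comparator: ">", threshold: 0.04}
  - label: plasmablast
    priority: 2
    predicates:
      - {feature: percBCR_high, comparator: ">", threshold: 0.15}
  - label: B cell naive
    priority: 3
    predicates:
      - {feature: pct_unmutated, comparator: ">", threshold: 0.8}
      - {feature: pct_IGHDM, comparator: ">", threshold: 0.98}
  - label: B cell memory
    priority: 4
    predicates:
      - {feature: mean_CD27, comparator: ">", threshold: 0.1}
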
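# The five archetype priors on the relative risk, applied to each
# treatment contrast versus placebo.
- label: minimally informative
  median_rr: 1.0
  sd_log: 10.0
- label: strongly enthusiastic
  median_rr: 0.6
  sd_log: 0.31
- label: moderately enthusiastic
  median_rr: 0.8
  sd_log: 0.14
- label: moderately skeptical
  median_rr: 1.0
  sd_log: 0.31
- label: strongly skeptical
  median_rr: 1.0
  sd_log: 0.14
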
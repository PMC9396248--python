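# Gamma-delta / cytotoxic-T subset decision list.  Cluster pre-assignments
# (CD2-negative gd cluster 31, SELL-high gd cluster 51) precede score rules.
name: gd_cd8
steps:
  - label: cd2neg_gd
    when: "cluster == 31"
  - label: sellhi_gd
    when: "cluster == 51"
  - label: cycling
    when: "m3 > 0.11 or t3 > 0.41"
  - label: activated
    when: "m1 > 0.25 or t1 >= 4 * t2"
fallback: cytotoxic
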
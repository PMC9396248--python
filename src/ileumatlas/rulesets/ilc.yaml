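# Innate-lymphoid-cell decision list.  Cluster 53 is the cycling group 1
# pre-assignment and cluster 43 the group 3 pre-assignment; remaining cells
# split into activated vs cytotoxic group 1.
name: ilc
steps:
  - label: cycling_group1
    when: "cluster == 53"
  - label: group3
    when: "cluster == 43"
  - label: activated_group1
    when: "t3 < 0.05 and (m2 > 0.4 or t2 > 0.9)"
fallback: cytotoxic_group1
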
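# B-lineage decision list.  Resting clusters {9, 13, 30}, transitioning
# cluster 33 and antibody-secreting cluster 25 are pre-assigned; remaining
# cells split into cycling vs activated.
name: b
steps:
  - label: resting
    when: "cluster in (9, 13, 30)"
  - label: transitioning
    when: "cluster == 33"
  - label: asc
    when: "cluster == 25"
  - label: cycling
    when: "m3 > 0.06 or t2 > 0.32"
fallback: activated
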
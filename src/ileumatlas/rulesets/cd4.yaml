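# Helper-T subset decision list: cycling first, then follicular vs activated.
name: cd4
steps:
  - label: cycling
    when: "m2 > 0.1 or t3 > 0.4"
  - label: follicular
    when: "m3 > 0.3 or t2 > t1"
fallback: activated
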
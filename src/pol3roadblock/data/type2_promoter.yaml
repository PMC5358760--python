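# Type-2 Pol III internal promoter model: canonical A/B box consensi
# (IUPAC) with a per-box mismatch budget and a spacer constraint measured
# from A-box end to B-box start (0-based half-open).
a_box:
  consensus: TRGCNNARYNNG
  max_mismatches: 2
b_box:
  consensus: GTTCRANNC
  max_mismatches: 2
spacer_range: [20, 40]
presets:
  strict-mir:
    # spacing characteristic of the conserved intronic MIR promoters
    spacer_range: [25, 26]
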
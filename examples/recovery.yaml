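# End-to-end run on the default recovery atlas: simulate -> qc -> classify
# (cluster + marker annotation) -> signatures -> consensus DE per cell type
# -> composition -> over-representation against the planted gene sets.
simulate:
  preset: recovery
classify:
  resolution: 0.3     # four well-separated programs
de:
  cell_types: all
composition:
  compartments:
    total: null
    luminal: [hs, av]
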
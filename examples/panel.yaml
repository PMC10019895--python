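# Panel for the synthetic default marker set: which channel is the nuclei
# stain, which channels feed the membrane composite plane, and which marker
# pairs are mutually exclusive (for false-positive scoring).
nuclei_channel: DNA
membrane_channels: [CD3, CD8, CD20, CD68, PanKeratin]
exclusive_pairs:
  - [CD3, CD20]
  - [PanKeratin, CD8]
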
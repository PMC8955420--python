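# 32-channel 10-20 montage in the Geneva ordering used by 32-electrode
# valence/arousal recordings.
name: deap32
channel_order:
  [FP1, AF3, F3, F7, FC5, FC1, C3, T7, CP5, CP1, P3, P7, PO3, O1, OZ, PZ,
   FP2, AF4, FZ, F4, F8, FC6, FC2, CZ, C4, T8, CP6, CP2, P4, P8, PO4, O2]
# 14 left-right homologous pairs
hemispheric_pairs:
  - [FP1, FP2]
  - [AF3, AF4]
  - [F3, F4]
  - [F7, F8]
  - [FC5, FC6]
  - [FC1, FC2]
  - [C3, C4]
  - [T7, T8]
  - [CP5, CP6]
  - [CP1, CP2]
  - [P3, P4]
  - [P7, P8]
  - [PO3, PO4]
  - [O1, O2]
# 13 frontal-posterior pairs
frontal_posterior_pairs:
  - [FC5, CP5]
  - [FC1, CP1]
  - [FC2, CP2]
  - [FC6, CP6]
  - [F7, P7]
  - [F3, P3]
  - [FZ, PZ]
  - [F4, P4]
  - [F8, P8]
  - [FP1, O1]
  - [FP2, O2]
  - [AF3, PO3]
  - [AF4, PO4]
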
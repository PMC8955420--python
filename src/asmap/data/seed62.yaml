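# 62-channel 10-20 montage in the distribution order of the 62-electrode
# reference cap. Channel order is an assumption documented in the README:
# the source material names the cap but never prints its ordering.
name: seed62
channel_order:
  [FP1, FPZ, FP2, AF3, AF4, F7, F5, F3, F1, FZ, F2, F4, F6, F8,
   FT7, FC5, FC3, FC1, FCZ, FC2, FC4, FC6, FT8,
   T7, C5, C3, C1, CZ, C2, C4, C6, T8,
   TP7, CP5, CP3, CP1, CPZ, CP2, CP4, CP6, TP8,
   P7, P5, P3, P1, PZ, P2, P4, P6, P8,
   PO7, PO5, PO3, POZ, PO4, PO6, PO8,
   CB1, O1, OZ, O2, CB2]
# 27 left-right homologous pairs (DASM / RASM)
hemispheric_pairs:
  - [FP1, FP2]
  - [AF3, AF4]
  - [F7, F8]
  - [F5, F6]
  - [F3, F4]
  - [F1, F2]
  - [FT7, FT8]
  - [FC5, FC6]
  - [FC3, FC4]
  - [FC1, FC2]
  - [T7, T8]
  - [C5, C6]
  - [C3, C4]
  - [C1, C2]
  - [TP7, TP8]
  - [CP5, CP6]
  - [CP3, CP4]
  - [CP1, CP2]
  - [P7, P8]
  - [P5, P6]
  - [P3, P4]
  - [P1, P2]
  - [PO7, PO8]
  - [PO5, PO6]
  - [PO3, PO4]
  - [CB1, CB2]
  - [O1, O2]
# 23 frontal-posterior pairs (DCAU)
frontal_posterior_pairs:
  - [FT7, TP7]
  - [FC5, CP5]
  - [FC3, CP3]
  - [FC1, CP1]
  - [FCZ, CPZ]
  - [FC2, CP2]
  - [FC4, CP4]
  - [FC6, CP6]
  - [FT8, TP8]
  - [F7, P7]
  - [F5, P5]
  - [F3, P3]
  - [F1, P1]
  - [FZ, PZ]
  - [F2, P2]
  - [F4, P4]
  - [F6, P6]
  - [F8, P8]
  - [FP1, O1]
  - [FPZ, OZ]
  - [FP2, O2]
  - [AF3, PO3]
  - [AF4, PO4]
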
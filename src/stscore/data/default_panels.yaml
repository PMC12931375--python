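# Default gene-set panels for spot-level positivity scoring.
# Positivity rule: a spot is positive when >= k_required panel genes have
# raw UMI count >= min_count (defaults 1 and 1).
isg:
  genes: [IFIT1, USP18, MX1, IFI27, IFI44L, OAS1]
apoptosis:
  genes: [CASP3, CASP8, BAX, BAK1, CYCS]
necroptosis:
  genes: [RIPK1, MLKL]
anchor_cd68:
  genes: [CD68]
# M1/M2 orientation per the IHC convention (CD16 = M1, CD163 = M2).
m1_markers:
  genes: [FCGR3A, FCGR1A]
m2_markers:
  genes: [CD163, ARG1]
# Opposite orientation, as some descriptions swap the pairs.
m1_markers_alt:
  genes: [CD163, ARG1]
m2_markers_alt:
  genes: [FCGR3A, FCGR1A]
m1_cytokines:
  genes: [IL1B, TNF, IL12B, IL18]
m2_cytokines:
  genes: [IL10, ARG1, TGFB1]
ifnb1:
  genes: [IFNB1]
tgfb1:
  genes: [TGFB1]
zbp1:
  genes: [ZBP1]
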
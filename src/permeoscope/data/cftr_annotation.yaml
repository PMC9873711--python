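# Annotation template for human CFTR (PDB 6MSM residue numbering).
#
# Helix spans are approximate transmembrane segments chosen to cover the
# pore-lining residues used by the analyses; adjust them to your structural
# model before use.  pore_helices lists the six helices lining the anion
# pathway; role tags name the residues the analyses track.
helices:
  TM1: [77, 110]
  TM2: [118, 145]
  TM3: [186, 215]
  TM4: [240, 270]
  TM5: [290, 320]
  TM6: [325, 360]
  TM7: [846, 875]
  TM8: [895, 930]
  TM9: [990, 1010]
  TM10: [1035, 1060]
  TM11: [1085, 1115]
  TM12: [1120, 1155]
pore_helices: [TM1, TM2, TM6, TM8, TM11, TM12]
roles:
  # axial origin of the pore coordinate system: T338 C-alpha
  origin: 338
  # hydrophobic bottleneck lining
  gate: [99, 102, 106, 337, 1137, 338, 1134]
  # inner-vestibule anion binding sites
  site1: [190, 248, 303]
  site2: [95, 98, 134]
  # Lys/Arg inventory of the TM region (charge-centre distributions)
  basic: [95, 104, 117, 134, 190, 248, 303, 334, 352, 1048, 1097]
  # extracellular helix-end anchors (interhelical distances, exit pathways)
  anchors:
    TM1: 106
    TM6: 334
    TM8: 914
    TM12: 1131
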
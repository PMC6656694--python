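# Marker-sign definitions of the core PBMC populations, arranged as a tree
# rooted at CD45+ leukocytes.  Levels: pos/neg are judged against the primary
# (positive/negative) cutoff of each antigen, high/low against the secondary
# cutoff.  Sibling profiles are mutually exclusive by construction so that a
# gated event descends through exactly one child.
profile: pbmc_core
populations:
  - {name: CD45+ leukocytes, parent: null,
     positive: [[CD45, pos]], negative: [[CD235ab, neg], [CD61, neg]]}

  # --- major lineages -----------------------------------------------------
  - {name: T cells, parent: CD45+ leukocytes,
     positive: [[CD3, pos]], negative: []}
  - {name: B cells, parent: CD45+ leukocytes,
     positive: [[CD19, pos], [HLA-DR, pos]], negative: [[CD3, neg]]}
  - {name: NK cells, parent: CD45+ leukocytes,
     positive: [[CD56, pos]], negative: [[CD3, neg], [CD19, neg], [CD14, neg]]}
  - {name: Monocytes, parent: CD45+ leukocytes,
     positive: [[CD14, pos], [CD33, pos]], negative: [[CD3, neg], [CD19, neg], [CD56, neg]]}
  - {name: cDC, parent: CD45+ leukocytes,
     positive: [[HLA-DR, pos], [CD11c, pos]],
     negative: [[CD14, neg], [CD3, neg], [CD19, neg], [CD56, neg], [CD123, neg]]}
  - {name: pDC, parent: CD45+ leukocytes,
     positive: [[CD123, pos], [HLA-DR, pos]],
     negative: [[CD11c, neg], [CD3, neg], [CD19, neg], [CD14, neg]]}
  - {name: Basophils, parent: CD45+ leukocytes,
     positive: [[FceRI, pos], [CD123, pos]],
     negative: [[HLA-DR, neg], [CD3, neg], [CD19, neg]]}

  # --- T-cell compartment -------------------------------------------------
  - {name: CD4 T cells, parent: T cells,
     positive: [[CD4, pos]], negative: [[CD8a, neg], [TCRgd, neg], [TCRVa24-Ja18, neg]]}
  - {name: CD8 T cells, parent: T cells,
     positive: [[CD8a, pos]], negative: [[CD4, neg], [TCRgd, neg], [TCRVa24-Ja18, neg]]}
  - {name: gd T cells, parent: T cells,
     positive: [[TCRgd, pos]], negative: [[TCRVa24-Ja18, neg]]}
  - {name: NKT cells, parent: T cells,
     positive: [[TCRVa24-Ja18, pos]], negative: [[TCRgd, neg]]}

  # CD45RA/CCR7 maturation scheme; the CD25-low clauses keep the conventional
  # subsets disjoint from Tregs.
  - {name: Naive CD4 T cells, parent: CD4 T cells,
     positive: [[CD45RA, pos], [CCR7, pos]], negative: [[CD45RO, neg], [CD25, low]]}
  - {name: Central memory CD4 T cells, parent: CD4 T cells,
     positive: [[CCR7, pos], [CD45RO, pos]], negative: [[CD45RA, neg], [CD25, low]]}
  - {name: Effector memory CD4 T cells, parent: CD4 T cells,
     positive: [[CD45RO, pos]], negative: [[CD45RA, neg], [CCR7, neg], [CD25, low]]}
  - {name: Effector CD4 T cells, parent: CD4 T cells,
     positive: [[CD45RA, pos]], negative: [[CCR7, neg], [CD45RO, neg], [CD25, low]]}
  - {name: Treg, parent: CD4 T cells,
     positive: [[CD25, high], [FoxP3, pos]], negative: [[CD127, low]]}

  - {name: Naive CD8 T cells, parent: CD8 T cells,
     positive: [[CD45RA, pos], [CCR7, pos]], negative: [[CD45RO, neg]]}
  - {name: Central memory CD8 T cells, parent: CD8 T cells,
     positive: [[CCR7, pos], [CD45RO, pos]], negative: [[CD45RA, neg]]}
  - {name: Effector memory CD8 T cells, parent: CD8 T cells,
     positive: [[CD45RO, pos]], negative: [[CD45RA, neg], [CCR7, neg]]}
  - {name: Effector CD8 T cells, parent: CD8 T cells,
     positive: [[CD45RA, pos]], negative: [[CCR7, neg], [CD45RO, neg]]}

  # --- B-cell maturation (CD27 / CD38) -------------------------------------
  - {name: CD27- B cells, parent: B cells,
     positive: [[HLA-DR, pos]], negative: [[CD27, neg], [CD38, low]]}
  - {name: CD27+ B cells, parent: B cells,
     positive: [[CD27, pos]], negative: [[CD38, low]]}
  - {name: Plasmablasts, parent: B cells,
     positive: [[CD27, pos], [CD38, high]], negative: []}

  # --- NK subsets (CD56 / CD16) --------------------------------------------
  - {name: CD56high CD16- NK cells, parent: NK cells,
     positive: [[CD56, high]], negative: [[CD16, neg]]}
  - {name: CD56low CD16+ NK cells, parent: NK cells,
     positive: [[CD16, pos]], negative: [[CD56, low]]}

  # --- monocyte subsets (CD14 / CD16) --------------------------------------
  - {name: Classical monocytes, parent: Monocytes,
     positive: [[CD14, high]], negative: [[CD16, neg]]}
  - {name: Intermediate monocytes, parent: Monocytes,
     positive: [[CD14, high], [CD16, pos]], negative: []}
  - {name: Non-classical monocytes, parent: Monocytes,
     positive: [[CD16, pos]], negative: [[CD14, low]]}
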
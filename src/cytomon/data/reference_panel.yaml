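# 33-antibody mass-cytometry reference panel for comprehensive immune
# monitoring, plus the auxiliary (non-antibody) channels the instrument
# records.  CD3, CD235ab and CD61 are in-house conjugates; their metal
# assignments (139La, 113In, 115In) are this package's packaging choice of
# conventional free channels.
name: reference-33
channels:
  - {metal_label: 89Y,   antigen: CD45,          clone: HI30,          category: lineage,    compartment: surface}
  - {metal_label: 113In, antigen: CD235ab,       clone: HIR2,          category: exclusion,  compartment: surface}
  - {metal_label: 115In, antigen: CD61,          clone: VI-PL2,        category: exclusion,  compartment: surface}
  - {metal_label: 139La, antigen: CD3,           clone: UCHT1,         category: lineage,    compartment: surface}
  - {metal_label: 142Nd, antigen: CD19,          clone: HIB19,         category: lineage,    compartment: surface}
  - {metal_label: 143Nd, antigen: CD117,         clone: 104D2,         category: lineage,    compartment: surface}
  - {metal_label: 144Nd, antigen: CD11b,         clone: ICRF44,        category: lineage,    compartment: surface}
  - {metal_label: 145Nd, antigen: CD4,           clone: RPA-T4,        category: lineage,    compartment: surface}
  - {metal_label: 146Nd, antigen: CD8a,          clone: RPA-T8,        category: lineage,    compartment: surface}
  - {metal_label: 147Sm, antigen: CD11c,         clone: BU15,          category: lineage,    compartment: surface}
  - {metal_label: 148Nd, antigen: CD14,          clone: RMO52,         category: lineage,    compartment: surface}
  - {metal_label: 150Nd, antigen: FceRI,         clone: AER-37/CRA-1,  category: lineage,    compartment: surface}
  - {metal_label: 151Eu, antigen: CD123,         clone: 6H6,           category: lineage,    compartment: surface}
  - {metal_label: 152Sm, antigen: TCRgd,         clone: 11F2,          category: lineage,    compartment: surface}
  - {metal_label: 153Eu, antigen: CD45RA,        clone: HI100,         category: subset,     compartment: surface}
  - {metal_label: 154Sm, antigen: Tim-3,         clone: F38-2E2,       category: checkpoint, compartment: surface}
  - {metal_label: 156Gd, antigen: PD-L1,         clone: 29E.2A3,       category: checkpoint, compartment: surface}
  - {metal_label: 158Gd, antigen: CD27,          clone: L128,          category: subset,     compartment: surface}
  - {metal_label: 160Gd, antigen: Tbet,          clone: 4B10,          category: subset,     compartment: intracellular}
  - {metal_label: 161Dy, antigen: CTLA-4,        clone: 14D3,          category: checkpoint, compartment: intracellular}
  - {metal_label: 162Dy, antigen: FoxP3,         clone: PCH101,        category: subset,     compartment: intracellular}
  - {metal_label: 163Dy, antigen: CD33,          clone: WM53,          category: lineage,    compartment: surface}
  - {metal_label: 164Dy, antigen: CD45RO,        clone: UCHL1,         category: subset,     compartment: surface}
  - {metal_label: 165Ho, antigen: CD127,         clone: A019D5,        category: subset,     compartment: surface}
  - {metal_label: 167Er, antigen: CCR7,          clone: G043H7,        category: subset,     compartment: surface}
  - {metal_label: 168Er, antigen: Ki-67,         clone: B56,           category: activation, compartment: intracellular}
  - {metal_label: 169Tm, antigen: CD25,          clone: 2A3,           category: subset,     compartment: surface}
  - {metal_label: 170Er, antigen: TCRVa24-Ja18,  clone: 6B11,          category: lineage,    compartment: surface}
  - {metal_label: 172Yb, antigen: CD38,          clone: HIT2,          category: subset,     compartment: surface}
  - {metal_label: 174Yb, antigen: HLA-DR,        clone: L243,          category: lineage,    compartment: surface}
  - {metal_label: 175Lu, antigen: PD-1,          clone: EH12.2H7,      category: checkpoint, compartment: surface}
  - {metal_label: 176Yb, antigen: CD56,          clone: NCAM16.2,      category: lineage,    compartment: surface}
  - {metal_label: 209Bi, antigen: CD16,          clone: 3G8,           category: lineage,    compartment: surface}
auxiliary_channels:
  - {name: DNA1,         metal_label: 191Ir, role: dna}
  - {name: DNA2,         metal_label: 193Ir, role: dna}
  - {name: Cisplatin,    metal_label: 195Pt, role: viability}
  - {name: Event_length, metal_label: '',    role: event_length}
  - {name: Bead,         metal_label: 140Ce, role: bead}
  - {name: BC1,          metal_label: 102Pd, role: barcode}
  - {name: BC2,          metal_label: 104Pd, role: barcode}
  - {name: BC3,          metal_label: 105Pd, role: barcode}
  - {name: BC4,          metal_label: 106Pd, role: barcode}
  - {name: BC5,          metal_label: 108Pd, role: barcode}
  - {name: BC6,          metal_label: 110Pd, role: barcode}
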
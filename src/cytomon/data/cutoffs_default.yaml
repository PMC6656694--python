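# Default positivity cutoffs on the arcsinh (cofactor 5) scale.
# primary separates negative from positive; secondary separates low from
# high expression (secondary > primary).  These are the generator's ground
# truth for the bundled synthetic profiles and the default "manual" cutoffs
# for gating them.
provenance: manual
antigens:
  default: {primary: 1.5, secondary: 3.0}
auxiliary:
  DNA1: {primary: 2.5, secondary: 6.0}       # secondary = doublet boundary
  DNA2: {primary: 2.5, secondary: 6.0}
  Cisplatin: {primary: 2.2, secondary: null}
  Event_length: {primary: 2.7, secondary: null}   # arcsinh(length/5)
  Bead: {primary: 3.0, secondary: null}
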
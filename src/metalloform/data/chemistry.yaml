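# Default adduct chemistry model.
# elements: atoms added by the adduct; hydrogen_displacement: protons lost
# on binding; cys_consumed: cysteine thiols occupied (budget bookkeeping).
adducts:
  Cu_I:
    elements: {Cu: 1}
    hydrogen_displacement: 1
    cys_consumed: 0
  Zn_II:
    elements: {Zn: 1}
    hydrogen_displacement: 2
    cys_consumed: 0
  Cd_II:
    elements: {Cd: 1}
    hydrogen_displacement: 2
    cys_consumed: 0
  NEM:
    elements: {C: 6, H: 7, N: 1, O: 2}
    hydrogen_displacement: 0
    cys_consumed: 1
  CAM:
    elements: {C: 2, H: 3, N: 1, O: 1}
    hydrogen_displacement: 0
    cys_consumed: 1
  SS:
    elements: {}
    hydrogen_displacement: 2
    cys_consumed: 2
  NtermAcetyl:
    elements: {C: 2, H: 2, O: 1}
    hydrogen_displacement: 0
    cys_consumed: 0
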
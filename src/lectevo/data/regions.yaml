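# Region map in the reference (ConI) numbering, 1-based inclusive intervals.
#
# The source alignment figure is not machine-readable, so these boundaries
# are editable defaults chosen to be consistent with every textual
# constraint (named substitution sites, loop segment strings, ligand
# contact residues); all analyses read this file rather than hard-coding
# boundaries.
reference: ConI
regions:
  NT: [1, 12]
  L2: [25, 31]
  L3: [36, 42]
  L4: [46, 52]
  L5: [69, 77]
  L6: [85, 92]
  CT: [110, 136]
# Display components used in mutant names, in their fixed order.
graft_components:
  N/C: [NT, CT]
  L5: [L5]
  L6: [L6]
  L3: [L3]
component_order: [N/C, L5, L6, L3]
# Sugar-binding residues whose ligand hydrogen bonds form their own groups.
ligand_residues:
  28: Lac-R28
  47: Lac-R47
# Loops participating in the MD cooperativity analysis.
md_loops: [L2, L3, L4, L5, L6]
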
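# Default RING-domain subtype rules.
#
# A RING domain is modelled as eight zinc-coordinating "metal ligand" residues
# (ML1..ML8, Cys/His with subtype-specific variants) separated by bounded
# residue gaps.  Gap ranges are inclusive counts of residues BETWEEN
# consecutive ligands.  The shared C3HC4/C3H2C3 consensus spacing gives a
# minimum feasible span of 8 + 22 = 30 residues.
#
# RING-v and RING-G are editable placeholder rules: verify their exact
# signatures and spacings against the Stone et al. (2005) Arabidopsis
# classification before using them on real proteomes.
max_domain_span: 102
incomplete_policy: flag
incomplete_min_ligands: 6
subtypes:
  - name: RING-H2
    ligands: [C, C, C, H, H, C, C, C]
    gaps: [[2, 2], [9, 39], [1, 3], [2, 3], [2, 2], [4, 48], [2, 2]]
    rbx_substitution: {ligand: 8, residue: D}
  - name: RING-HC
    ligands: [C, C, C, H, C, C, C, C]
    gaps: [[2, 2], [9, 39], [1, 3], [2, 3], [2, 2], [4, 48], [2, 2]]
  - name: RING-v
    ligands: [C, C, C, C, H, C, C, C]
    gaps: [[2, 2], [9, 39], [1, 3], [1, 5], [2, 2], [2, 48], [2, 2]]
  - name: RING-G
    ligands: [C, C, C, H, G, C, C, C]
    gaps: [[2, 2], [9, 39], [1, 3], [2, 3], [2, 2], [4, 48], [2, 2]]
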
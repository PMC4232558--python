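# Versioned pharmacophore feature-typing rule table.
#
# Six classical feature classes. Counting modes:
#   atoms   - number of distinct atoms matched by any pattern in the list
#   matches - number of substructure (group) matches
#   rings   - number of aromatic rings (no SMARTS needed)
#
# A/D follow Lipinski-style definitions (acceptors: N or O atoms; donors:
# N-H or O-H). H counts hydrophobic atoms: non-aromatic carbons with no
# bonded heteroatom, so a large aliphatic skeleton contributes in
# proportion to its bulk. N/P are ionization states expected at pH 7.
version: 1
features:
  A:
    description: H-bond acceptor (nitrogen or oxygen atom)
    mode: atoms
    smarts:
      - "[#7]"
      - "[#8]"
  D:
    description: H-bond donor (N-H or O-H)
    mode: atoms
    smarts:
      - "[#7;!H0]"
      - "[#8;!H0]"
  H:
    description: hydrophobic atom (aliphatic carbon with no heteroatom neighbour)
    mode: atoms
    smarts:
      - "[C;!$(C~[#7,#8,#15,#16,F,Cl,Br,I])]"
  N:
    description: negatively ionizable group at pH 7 (carboxylic, sulfonic or phosphonic acid)
    mode: matches
    smarts:
      - "[CX3](=O)[OX2H1]"
      - "[CX3](=O)[O-]"
      - "[SX4](=O)(=O)[OX2H1,OX1-]"
      - "[PX4](=O)([OX2H1,OX1-])[OX2H1,OX1-]"
  P:
    description: positively ionizable group at pH 7 (aliphatic amine, amidinium, guanidinium)
    mode: matches
    smarts:
      - "[NX3;+0;!$([N]~[!#6;!#1]);!$([N]C=[#7,#8,#16]);!$([N]a)]"
      - "[NX4+,NX3+]"
      - "[CX3](=[NX2])[NX3]"
  R:
    description: aromatic ring
    mode: rings
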
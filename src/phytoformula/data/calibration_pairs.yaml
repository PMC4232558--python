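# Curated feature-similarity labels for compound pairs with a shared
# protein target, used to calibrate the similar/dissimilar verdict
# threshold (midpoint between the lowest similar-pair score and the
# highest dissimilar-pair score).
#
# "similar" pairs: the two pentacyclic triterpene acids (betulinic and
# oleanolic acid); the two 4',7-dihydroxyisoflavones (diadzein and
# genistein); and all pairs among the ten aldose-reductase binders, which
# share a common polyphenolic feature pattern.  "dissimilar" pairs: a
# triterpene against an isoflavone (betulinic acid / diadzein) and a
# triterpene acid against a small phenolic acid (oleanolic / gallic acid).
similar:
  - pair: [AC3, AC5]
    anchor: S7-betulinic-oleanolic
  - pair: [AC42, AC15]
    anchor: Fig12-diadzein-genistein
  - group: aldose-reductase-binders
    anchor: Fig8-caption
dissimilar:
  - pair: [AC3, AC42]
    anchor: S7-betulinic-diadzein
  - pair: [AC5, AC11]
    anchor: Fig13-oleanolic-gallic
aldose_reductase_binders: [AC9, AC13, AC12, AC11, AC37, AC7, AC16, AC32, AC14, AC31]
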
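code,name,smiles,provenance
AC2,1-Deoxynojirimycin,OC[C@H]1NC[C@H](O)[C@@H](O)[C@@H]1O,standard-identity
AC3,Betulinic acid,CC(=C)C1CCC2(CCC3(C)C(CCC4C3(C)CCC3C(C)(C)C(O)CCC34C)C12)C(O)=O,standard-identity
AC4,Beta sitosterol,CCC(CCC(C)C1CCC2C3CC=C4CC(O)CCC4(C)C3CCC12C)C(C)C,standard-identity
AC5,Oleanolic acid,CC1(C)CCC2(CCC3(C)C(=CCC4C5(C)CCC(O)C(C)(C)C5CCC34C)C2C1)C(O)=O,standard-identity
AC6,Myricetin,O=C1C(O)=C(c2cc(O)c(O)c(O)c2)Oc2cc(O)cc(O)c21,standard-identity
AC7,Kaempferol,O=C1C(O)=C(c2ccc(O)cc2)Oc2cc(O)cc(O)c21,standard-identity
AC9,Apigenin,O=C1C=C(c2ccc(O)cc2)Oc2cc(O)cc(O)c21,standard-identity
AC11,Gallic acid,O=C(O)c1cc(O)c(O)c(O)c1,standard-identity
AC12,Ellagic acid,O=c1oc2c(O)c(O)cc3c(=O)oc4c(O)c(O)cc1c4c23,standard-identity
AC13,Astragalin,OC[C@H]1O[C@@H](OC2=C(c3ccc(O)cc3)Oc3cc(O)cc(O)c3C2=O)[C@H](O)[C@@H](O)[C@@H]1O,standard-identity
AC14,Quercetin,O=C1C(O)=C(c2ccc(O)c(O)c2)Oc2cc(O)cc(O)c21,standard-identity
AC15,Genistein,O=C1C(c2ccc(O)cc2)=COc2cc(O)cc(O)c21,standard-identity
AC16,Luteolin,O=C1C=C(c2ccc(O)c(O)c2)Oc2cc(O)cc(O)c21,standard-identity
AC31,Rosmarinic acid,O=C(O)C(Cc1ccc(O)c(O)c1)OC(=O)/C=C/c1ccc(O)c(O)c1,standard-identity
AC32,Perilloside A,OC[C@H]1O[C@@H](OCC2=CCC(C(=C)C)CC2)[C@H](O)[C@@H](O)[C@@H]1O,standard-identity
AC37,Gallocatechin,O[C@@H]1Cc2c(O)cc(O)cc2O[C@@H]1c1cc(O)c(O)c(O)c1,standard-identity
AC39,Bakuchicin,O=c1ccc2cc3ccoc3cc2o1,standard-identity(furanocoumarin)
AC40,Corylifolin,O=C1C(c2ccc(O)c(CC=C(C)C)c2)=COc2cc(O)ccc21,standard-identity(neobavaisoflavone-type)
AC41,Bakuchiol,C=CC(C)(/C=C/c1ccc(O)cc1)CCC=C(C)C,standard-identity
AC42,Diadzein,O=C1C(c2ccc(O)cc2)=COc2cc(O)ccc21,standard-identity
AC43,Stigmasterol,CCC(/C=C/C(C)C1CCC2C3CC=C4CC(O)CCC4(C)C3CCC12C)C(C)C,standard-identity
AC44,Pinoresinol,COc1cc(C2OCC3C2COC3c2ccc(O)c(OC)c2)ccc1O,standard-identity
AC49,Coniferin,COc1cc(/C=C/CO)ccc1O[C@@H]1O[C@H](CO)[C@@H](O)[C@H](O)[C@H]1O,standard-identity
AC54,Shogaol,CCCCC/C=C/C(=O)CCc1ccc(O)c(OC)c1,standard-identity(6-shogaol)
AC58,Wedelolactone,COc1cc(O)c2c3oc4cc(O)c(O)cc4c3c(=O)oc2c1,standard-identity
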
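code	name	aliases
AC1	Synephrine
AC2	1-Deoxynojirimycin	DNJ
AC3	Betulinic acid
AC4	Beta sitosterol
AC5	Oleanolic acid
AC6	Myricetin
AC7	Kaempferol
AC9	Apigenin
AC10	Ferulic acid
AC11	Gallic acid
AC12	Ellagic acid
AC13	Astragalin	Kaempferol 3-O-glucoside
AC14	Quercetin
AC15	Genistein
AC16	Luteolin
AC17	Mangiferin
AC18	Salacinol
AC19	Kotalanol
AC20	(-)-Epigallocatechin
AC21	(-)-Epicatechin-(4beta->8)-(-)-4'-O-methylepigallocatechin
AC22	(-)-Epicatechin
AC23	3-beta dihydroxyolean-12-en-29-oic acid
AC24	22-beta dihydroxyolean-12-en-29-oic acid
AC25	Berberine
AC26	Avenasterol
AC27	Amyrin
AC30	Protocatechuic acid
AC31	Rosmarinic acid
AC32	Perilloside A
AC33	Perilloside C
AC34	Beta estradiol
AC35	Kaempferol-3-o-glucoside
AC36	Delphinidin
AC37	Gallocatechin
AC38	Angelicin
AC39	Bakuchicin
AC40	Corylifolin
AC41	Bakuchiol
AC42	Diadzein	Daidzein
AC43	Stigmasterol
AC44	Pinoresinol
AC45	Arachidonic acid
AC46	Folic acid
AC47	Guaiacol
AC48	Oleic acid
AC49	Coniferin
AC50	Palmitic acid
AC51	Stearic acid
AC52	Linolenic acid
AC53	Pipecolic acid
AC54	Shogaol
AC55	Geraniol
AC56	Isoquercitrin
AC57	Diosgenin
AC58	Wedelolactone
AC59	Marmesin
AC60	Beta glucan
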
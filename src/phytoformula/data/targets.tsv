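code	name	aliases
PT1	Mono amine oxidase
PT2	Glucosidase
PT3	Alpha glucosidase
PT5	Glycogen debranching enzyme
PT6	Cytosolic beta glucosidase
PT7	Lactase glycosylceramidase
PT8	Glucosidase II beta subunit precursor
PT9	Diacylglycerol acyltransferase
PT10	Nitric oxide synthase
PT11	5-alpha reductase
PT12	Glycogen phosphorylase
PT13	Gaba transaminase
PT14	Alpha amylase
PT15	Xanthine oxidase
PT16	Aldose reductase
PT21	20-alpha hydroxysteroid dehydrogenase
PT22	Carbonic anhydrase
PT23	Udp glucose dehydrogenase
PT24	Ribonucleotide reductase
PT25	COX 1
PT26	COX 2
PT27	Steroid-5-alpha reductase type II
PT29	Pancreatic lipase
PT30	Lipoprotein lipase
PT31	AMPK
PT32	Caspase 3
PT34	Catechol-o-methyltransferase
PT35	Estrogen receptor
PT36	MAPK
PT37	Glyoxalase
PT38	DNA topoisomerase 2
PT39	DNA Polymerase
PT40	DNA Polymerase beta
PT41	Phospholipase A2
PT42	Glutamate dehydrogenase
PT43	Glutathione transferase
PT44	Pyruvate dehydrogenase
PT45	Protein tyrosine phosphatase
PT46	Thromboxane synthase
PT47	IKK beta
PT48	Acetylcholine esterase
PT49	IGF
PT50	NADPH oxidase
PT51	Insulin receptor
PT52	PI3K
PT53	Lipoxygenase
PT54	Maltase glucoamylase
PT55	Beta secretase1 (BACE1)
PT56	NFK-beta
PT57	PSORS1C2
PT58	Lysosomal alpha glucosidase precursor
PT59	Tyrosine phosphatase 1B
PT60	LXR alpha
PT61	DNA topoisomerase 1
PT62	Protein tyrosine phosphatase 1B
PT63	NA+/K+ -ATPase
PT64	3-Beta hydroxysteroid dehydrogenase type II
PT65	Quinone reductase 2
PT66	CARM1
PT67	Protein tyrosine kinase
PT68	IGFR
PT69	Sucrase isomaltase n-terminal domains
PT70	7-Dehydrocholesterol reductase
PT71	Protein tyrosine kinase IIB
PT72	FABP4
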
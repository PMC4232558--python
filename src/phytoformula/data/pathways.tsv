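code	name
P1	Aminoacid metabolism
P2	Glycogen degradation
P3	N-Glycan biosynthesis
P4	Starch and sucrose metabolism
P5	Galactose metabolism
P6	Glycerolipid metabolism
P7	Apoptosis
P8	Steroid hormone biosynthesis
P9	Starch degradation-I
P10	Carbohydrate digestion and absorption
P11	Pancreatic secretion
P12	Purine metabolism
P13	Fructose and mannose metabolism
P14	Glycolysis/Gluconeogenesis
P18	Nitrogen metabolism
P19	Arachidonic acid metabolism
P20	Sucrose metabolic process
P21	Retinoid metabolism and transport
P22	PPAR signaling pathway
P23	Insulin signaling pathway
P24	BDNF signaling pathway
P25	STAT3 signaling pathway
P26	Aldosterone-regulated sodium reabsorption
P27	Pyruvate metabolism
P28	Cell cycle and DNA replication
P29	Alpha-linolenic acid metabolism
P30	Linoleic acid metabolism
P31	Glutamine biosynthesis
P32	Glutathione metabolism
P33	Metabolism of xenobiotics by CYP450
P34	Drug metabolism by CYP450
P35	Citrate cycle (TCA cycle)
P36	JAK-STAT cascade in growth hormone signaling pathway
P37	MAPK signaling pathway
P38	Chemokine signaling pathway
P40	NFKB activation
P41	Leukocyte endothelial migration
P42	Osteoclast differentiation
P43	ROS generation and oxidative stress
P44	Adherens junction
P45	Inositol phosphate metabolism
P46	Phosphatidylinositol signaling pathway
P47	JAG1-NOTCH pathway
P48	Toll-like receptor signaling pathway
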
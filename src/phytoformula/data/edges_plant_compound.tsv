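source	target	kind	evidence
ADP2	AC2	contains	Hypothesis1-inference
ADP21	AC3	contains	Hypothesis1-inference
ADP5	AC5	contains	Discussion-formulation
ADP3	AC6	contains	Discussion-formulation
ADP21	AC11	contains	Hypothesis1-inference
ADP27	AC11	contains	Hypothesis1-inference
ADP23	AC54	contains	Hypothesis2-inference
ADP25	AC58	contains	Hypothesis1-inference
ADP23	AC55	contains	curated-assumption(ginger-geraniol)
ADP14	AC32	contains	curated-assumption(perilla-perilloside)
ADP14	AC33	contains	curated-assumption(perilla-perilloside)
ADP17	AC39	contains	curated-assumption(psoralea)
ADP17	AC40	contains	curated-assumption(psoralea)
ADP17	AC41	contains	curated-assumption(psoralea)
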
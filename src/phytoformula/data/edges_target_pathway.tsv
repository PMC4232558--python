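source	target	kind	evidence
PT3	P3	participates_in	Discussion-AC2
PT3	P20	participates_in	Discussion-AC2
PT5	P2	participates_in	Discussion-AC2
PT6	P4	participates_in	Discussion-AC2
PT7	P5	participates_in	Discussion-AC2
PT9	P6	participates_in	Discussion-AC3
PT11	P8	participates_in	Discussion-AC3
PT12	P2	participates_in	Discussion-AC3
PT13	P1	participates_in	Discussion-AC5
PT14	P11	participates_in	Discussion-AC6
PT14	P4	participates_in	Discussion-AC6
PT14	P9	participates_in	synthetic-padding
PT14	P10	participates_in	synthetic-padding
PT16	P13	participates_in	Discussion-AC11
PT16	P5	participates_in	Discussion-AC11
PT16	P6	participates_in	Discussion-AC11
PT23	P4	participates_in	Discussion-AC11
PT24	P19	participates_in	Discussion-AC11
PT25	P19	participates_in	Discussion-AC5
PT26	P19	participates_in	Discussion-AC5
PT47	P40	participates_in	synthetic-padding
PT47	P23	participates_in	synthetic-padding
PT47	P48	participates_in	synthetic-padding
PT47	P42	participates_in	synthetic-padding
PT52	P46	participates_in	synthetic-padding
PT52	P45	participates_in	synthetic-padding
PT52	P23	participates_in	synthetic-padding
PT52	P38	participates_in	synthetic-padding
PT56	P7	participates_in	Discussion-AC54
PT56	P40	participates_in	synthetic-padding
PT56	P48	participates_in	synthetic-padding
PT56	P42	participates_in	synthetic-padding
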
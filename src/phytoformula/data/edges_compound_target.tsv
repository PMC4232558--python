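source	target	kind	evidence
AC2	PT3	targets_direct	Discussion-AC2
AC2	PT5	targets_indirect	Discussion-AC2
AC2	PT6	targets_indirect	Discussion-AC2
AC2	PT7	targets_indirect	Discussion-AC2
AC2	PT8	targets_indirect	Discussion-AC2
AC3	PT9	targets_direct	Discussion-AC3
AC3	PT11	targets_direct	Discussion-AC3
AC3	PT12	targets_direct	Discussion-AC3
AC3	PT38	targets_direct	Discussion-AC3
AC3	PT40	targets_direct	Discussion-AC3
AC3	PT60	targets_direct	Discussion-AC3
AC3	PT10	targets_indirect	Discussion-AC3
AC3	PT50	targets_indirect	Discussion-AC3
AC4	PT11	targets_direct	Hypothesis2-inference
AC5	PT9	targets_direct	Discussion-AC5
AC5	PT12	targets_direct	Discussion-AC5
AC5	PT13	targets_direct	Discussion-AC5
AC5	PT25	targets_direct	Discussion-AC5
AC5	PT26	targets_direct	Discussion-AC5
AC5	PT40	targets_direct	Discussion-AC5
AC6	PT14	targets_direct	Discussion-AC6
AC6	PT15	targets_direct	Discussion-AC6
AC6	PT51	targets_direct	Discussion-AC6
AC6	PT52	targets_direct	Discussion-AC6
AC7	PT16	targets_direct	Fig8-caption
AC7	PT53	targets_direct	curated-assumption(S7-gallic-acid)
AC9	PT16	targets_direct	Fig8-caption
AC9	PT21	targets_direct	curated-assumption(S7-gallic-acid)
AC11	PT16	targets_direct	Discussion-AC11
AC11	PT23	targets_direct	Discussion-AC11
AC11	PT24	targets_direct	Discussion-AC11
AC11	PT25	targets_direct	Discussion-AC11
AC11	PT26	targets_direct	Discussion-AC11
AC12	PT16	targets_direct	Fig8-caption
AC13	PT16	targets_direct	Fig8-caption
AC14	PT16	targets_direct	Fig8-caption
AC15	PT38	targets_direct	Fig12-caption
AC16	PT16	targets_direct	Fig8-caption
AC16	PT3	targets_direct	Fig11-caption
AC31	PT16	targets_direct	Fig8-caption
AC32	PT16	targets_direct	Fig8-caption
AC37	PT16	targets_direct	Fig8-caption
AC39	PT38	targets_direct	Fig12-caption
AC40	PT39	targets_direct	Fig9-caption
AC41	PT39	targets_direct	Fig9-caption
AC42	PT39	targets_direct	S7-diadzein
AC42	PT38	targets_direct	S7-diadzein
AC43	PT40	targets_direct	Fig10-caption
AC44	PT3	targets_direct	Fig11-caption
AC49	PT25	targets_direct	Fig13-caption
AC54	PT56	targets_direct	Discussion-AC54
AC54	PT26	targets_indirect	Discussion-AC54
AC54	PT36	targets_indirect	Discussion-AC54
AC58	PT3	targets_direct	Discussion-AC58
AC58	PT47	targets_direct	Discussion-AC58
AC60	PT3	targets_direct	Fig11-caption
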
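source	target	kind	evidence
PT16	D10	implicated_in	Discussion-AC11
PT16	D12	implicated_in	Discussion-AC11
PT47	D8	implicated_in	Discussion-AC58
PT56	D7	implicated_in	Discussion-AC54
PT56	D10	implicated_in	Discussion-AC54
PT56	D12	implicated_in	Discussion-AC54
PT36	D9	implicated_in	Discussion-AC54
PT36	D12	implicated_in	Discussion-AC54
PT15	D7	implicated_in	Discussion-AC6
PT10	D10	implicated_in	Discussion-AC3
PT38	D13	implicated_in	Discussion-AC3
PT40	D13	implicated_in	Discussion-AC11
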
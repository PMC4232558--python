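code	name
D1	Cancer
D2	Parkinson's disease
D3	Alzheimer's disease
D4	Ischemia
D5	Hepatitis
D6	Liver disease
D7	Type 1 diabetes
D8	Type 2 diabetes
D9	Diabetic neuropathy
D10	Diabetic nephropathy
D11	Diabetic angiopathy
D12	Diabetic retinopathy
D13	Hyperglycemia
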
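# Condensation + decarboxylating cleavage: exercises convolution EMUs and
# a balanced intracellular CO2 pool.
#! external: S.x
id	equation	reversible	pathway	notes
src	S.x (abc) -> A (abc)	0	toy
cond	A (abc) + A (def) -> H (abcdef)	1	toy
dec	H (abcdef) -> P (abcde) + CO2 (f)	0	toy
pout	P ->	0	toy
cout	CO2 ->	0	toy
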
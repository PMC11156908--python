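# Reversible chain with exchange fluxes and an atom rotation.
#! external: S.x
id	equation	reversible	pathway	notes
src	S.x (ab) -> A (ab)	0	toy
r1	A (ab) -> B (ab)	1	toy
r2	B (ab) -> C (ba)	1	toy
out	C ->	0	toy
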
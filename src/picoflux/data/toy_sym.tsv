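# Symmetric intermediate: only carbon 1 arrives labeled, downstream
# positions 1 and 4 must equilibrate by 50/50 scrambling.
#! external: C.x, U.x
#! symmetric: SYM
id	equation	reversible	pathway	notes
s1	C.x (a) + U.x (bcd) -> A (abcd)	0	toy
s2	A (abcd) -> SYM (abcd)	0	toy
s3	SYM (abcd) -> M (abcd)	0	toy
out	M ->	0	toy
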
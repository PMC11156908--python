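# Minimal single-compartment photoautotroph network for statistical
# studies (parameter recovery, CI coverage, SSR calibration).  Keeps the
# TG2-like topology: carbon fixation with a regenerated C2 acceptor,
# storage and protein sinks, anaplerosis, an effectively inactive
# AKG->succinate branch (SUC symmetric), and the malic-enzyme shuttle.
#! external: CO2.x
#! symmetric: SUC
id	equation	reversible	pathway	notes
src	CO2.x (a) -> CO2 (a)	0	uptake
fix	ACP (ab) + CO2 (c) -> PGA (cab)	0	cbb
red	PGA (abc) -> TP (abc)	1	cbb
reg	TP (abc) + TP (def) -> ACP (ab) + ACP (cd) + ACP (ef)	0	cbb	carbon-conserving acceptor regeneration
pyk	TP (abc) -> PYR (abc)	0	glycolysis
ppc	TP (abc) + CO2 (d) -> OAA (abcd)	0	anaplerosis
pdh	PYR (abc) -> ACA (bc) + CO2 (a)	0	tca
cs	OAA (abcd) + ACA (ef) -> AKG (dcbae) + CO2 (f)	0	tca
akgsuc	AKG (abcde) -> SUC (bcde) + CO2 (a)	0	tca	inactive branch
fum	SUC (abcd) -> MAL (abcd)	0	tca
mdh	MAL (abcd) -> OAA (abcd)	1	tca
me	MAL (abcd) -> PYR (abc) + CO2 (d)	0	tca	malic enzyme
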
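# Reduced photoautotroph core network used by the synthetic labeling scenarios.
# CBB carbon fixation keeps a C5 acceptor pool (RuP) with a lumped,
# carbon-conserving 5 TP -> 3 RuP regeneration step; storage goes through a
# hexose-phosphate pool to G1P, lower glycolysis is cytosolic behind a
# triose-phosphate transporter, and the TCA cycle is complete but with an
# independently estimable AKG->succinate branch and a malate->pyruvate
# (malic enzyme) shuttle.  Compartments: .h chloroplast, .c cytosol,
# .m mitochondria, .x external.
#! external: CO2.x
#! symmetric: SUC.m
id	equation	reversible	pathway	notes
src	CO2.x (a) -> CO2.h (a)	0	uptake	net inorganic carbon uptake
fix	RuP.h (abcde) + CO2.h (f) -> PGA.h (cba) + PGA.h (def)	0	cbb	carboxylation of the C5 acceptor
red	PGA.h (abc) -> TP.h (abc)	1	cbb	reduction (PGK+GAPDH+TPI lumped)
reg	TP.h (abc) + TP.h (def) + TP.h (ghi) + TP.h (jkl) + TP.h (mno) -> RuP.h (abcde) + RuP.h (fghij) + RuP.h (klmno)	0	cbb	acceptor regeneration (TK/TA/aldolase lump)
ald	TP.h (abc) + TP.h (def) -> HP.h (cbadef)	1	starch	aldolase/FBPase lump to hexose phosphate
pgm	HP.h (abcdef) -> G1P.h (abcdef)	1	starch	phosphoglucomutase branch to storage
tpt	TP.h (abc) -> TP.c (abc)	1	transport	triose phosphate transporter
pyk	TP.c (abc) -> PYR.c (abc)	0	glycolysis	lower glycolysis lump
ppc	TP.c (abc) + CO2.c (d) -> OAA.m (abcd)	0	anaplerosis	PEP carboxylase lump
pdh	PYR.c (abc) -> ACA.m (bc) + CO2.m (a)	0	tca	pyruvate dehydrogenase
cs	OAA.m (abcd) + ACA.m (ef) -> AKG.m (dcbae) + CO2.m (f)	0	tca	citrate synthase + aconitase + IDH lump
akgsuc	AKG.m (abcde) -> SUC.m (bcde) + CO2.m (a)	0	tca	AKG dehydrogenase + succinyl-CoA ligase
fum	SUC.m (abcd) -> MAL.m (abcd)	0	tca	SDH + fumarase lump; inactive branch
mdh	MAL.m (abcd) -> OAA.m (abcd)	1	tca	malate dehydrogenase
me	MAL.m (abcd) -> PYR.c (abc) + CO2.m (d)	0	tca	NADP malic enzyme shuttle
co2mc	CO2.m (a) -> CO2.c (a)	0	transport	respiratory CO2 export
co2ch	CO2.c (a) -> CO2.h (a)	1	transport	CO2 return for refixation
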
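# Compartmentalized CBB + photorespiration + glycolysis + incomplete-TCA
# network with explicit pentose-phosphate regeneration, distilled from the
# central-carbon flux map of a fast-growing picoalga.  The glyoxylate shunt
# is deliberately absent.  Compartments: .h chloroplast, .c cytosol,
# .m mitochondria, .x external.
#! external: CO2.x
#! symmetric: SUC.m, FUM.m
#! dilution: PGA.h, TP.h, F6P.h, G1P.h, PEP.c, PYR.c, CIT.m, AKG.m, SUC.m, FUM.m, MAL.m
id	equation	reversible	pathway	notes
rbc_c	RuBP.h (abcde) + CO2.h (f) -> PGA.h (cba) + PGA.h (def)	0	cbb	RuBisCO carboxylase
pgk	PGA.h (abc) -> TP.h (abc)	1	cbb	PGK+GAPDH+TPI lump
fba	TP.h (abc) + TP.h (def) -> FBP.h (cbadef)	1	cbb	fructose-bisphosphate aldolase
fbp	FBP.h (abcdef) -> F6P.h (abcdef)	0	cbb	FBPase
tkt1	F6P.h (abcdef) + TP.h (ghi) -> X5P.h (abghi) + E4P.h (cdef)	1	cbb	transketolase
sba	E4P.h (abcd) + TP.h (efg) -> SBP.h (gfeabcd)	1	cbb	SBP aldolase
sbp	SBP.h (abcdefg) -> S7P.h (abcdefg)	0	cbb	SBPase
tkt2	S7P.h (abcdefg) + TP.h (hij) -> X5P.h (abhij) + R5P.h (cdefg)	1	cbb	transketolase
rpe	X5P.h (abcde) -> Ru5P.h (abcde)	1	cbb	ribulose-phosphate epimerase
rpi	R5P.h (abcde) -> Ru5P.h (abcde)	1	cbb	ribose-phosphate isomerase
prk	Ru5P.h (abcde) -> RuBP.h (abcde)	0	cbb	phosphoribulokinase
pgi	F6P.h (abcdef) -> G6P.h (abcdef)	1	starch	glucose-6-phosphate isomerase
pgm	G6P.h (abcdef) -> G1P.h (abcdef)	1	starch	phosphoglucomutase
rbc_o	RuBP.h (abcde) -> PGA.h (cde) + PG2.h (ba)	0	photorespiration	RuBisCO oxygenase
pgp	PG2.h (ab) -> GA.h (ab)	0	photorespiration	phosphoglycolate phosphatase
gox	GA.h (ab) -> GLY.h (ab)	0	photorespiration	glycolate oxidation + transamination lump
gdc	GLY.h (ab) + GLY.h (cd) -> SER.h (cdb) + CO2.h (a)	0	photorespiration	glycine decarboxylase + SHMT
sgat	SER.h (abc) -> PGA.h (abc)	0	photorespiration	serine to glycerate to 3PGA lump
tpt3	TP.h (abc) -> TP.c (abc)	1	transport	triose phosphate transporter
gapc	TP.c (abc) -> PGA.c (abc)	1	glycolysis	cytosolic GAPDH/PGK lump
eno	PGA.c (abc) -> PEP.c (abc)	1	glycolysis	phosphoglycerate mutase + enolase
pyk	PEP.c (abc) -> PYR.c (abc)	0	glycolysis	pyruvate kinase
ppc	PEP.c (abc) + CO2.c (d) -> OAA.c (abcd)	0	anaplerosis	PEP carboxylase
ppt	PEP.c (abc) -> PEP.h (abc)	1	transport	PEP transporter into the chloroplast
pdc	PEP.h (abc) -> ACA.h (bc) + CO2.h (a)	0	lipid	plastid PK + pyruvate dehydrogenase lump
pyrt	PYR.c (abc) -> PYR.m (abc)	0	transport	pyruvate import into mitochondria
pdh	PYR.m (abc) -> ACA.m (bc) + CO2.m (a)	0	tca	pyruvate dehydrogenase
cs	OAA.m (abcd) + ACA.m (ef) -> CIT.m (dcbafe)	0	tca	citrate synthase
idh	CIT.m (abcdef) -> AKG.m (abcde) + CO2.m (f)	0	tca	aconitase + isocitrate dehydrogenase
akgd	AKG.m (abcde) -> SUC.m (bcde) + CO2.m (a)	0	tca	AKG dehydrogenase + succinyl-CoA ligase
sdh	SUC.m (abcd) -> FUM.m (abcd)	1	tca	succinate dehydrogenase
fh	FUM.m (abcd) -> MAL.m (abcd)	1	tca	fumarase, high exchange
mdh	MAL.m (abcd) -> OAA.m (abcd)	1	tca	malate dehydrogenase
me	MAL.m (abcd) -> PYR.m (abc) + CO2.m (d)	0	tca	NADP malic enzyme
oaat	OAA.c (abcd) -> OAA.m (abcd)	0	transport	oxaloacetate shuttle lump
co2u	CO2.x (a) -> CO2.h (a)	0	uptake	net inorganic carbon uptake
co2mc	CO2.m (a) -> CO2.c (a)	0	transport	respiratory CO2 export
co2ch	CO2.c (a) -> CO2.h (a)	1	transport	CO2 return for refixation
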
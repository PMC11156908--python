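# Monomer/precursor stoichiometry for the core scenario network.
# monomer_mass = g/mol of the residue as polymerized; coef = mmol precursor
# per mmol monomer; carbons = carbons contributed by one precursor unit.
# Protein amino acids are grouped into four precursor families; the default
# weights are an even profile, overridden per strain at run time.
macromolecule,monomer,monomer_mass,weight,precursor,coef,carbons
carbohydrate,anhydroglucose,162.14,1.0,G1P.h,1.0,6
protein,ala_like,71.1,0.25,PYR.c,1.0,3
protein,asp_like,115.1,0.25,OAA.m,1.0,4
protein,glu_like,129.1,0.25,AKG.m,1.0,5
protein,ser_like,75.0,0.25,PGA.h,1.0,3
fame,c16_acyl,256.4,1.0,ACA.m,8.0,2
dna,dnmp_residue,309.0,1.0,TP.h,2.0,3
dna,dnmp_residue,309.0,1.0,PGA.h,1.25,3
rna,nmp_residue,321.0,1.0,TP.h,2.0,3
rna,nmp_residue,321.0,1.0,PGA.h,1.25,3
chla,chlorophyll_a,893.5,1.0,AKG.m,8.0,5
chla,chlorophyll_a,893.5,1.0,PYR.c,5.0,3
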
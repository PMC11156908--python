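# Monomer/precursor stoichiometry for the full compartmentalized network.
# Same layout as monomers_core.csv; aromatic amino acids draw E4P + 2 PEP
# through the shikimate route, fatty acids are made in the chloroplast from
# acetyl-CoA supplied via the PEP transporter.
macromolecule,monomer,monomer_mass,weight,precursor,coef,carbons
carbohydrate,anhydroglucose,162.14,1.0,G1P.h,1.0,6
protein,ala_like,71.1,0.22,PYR.c,1.0,3
protein,asp_like,115.1,0.22,OAA.m,1.0,4
protein,glu_like,129.1,0.22,AKG.m,1.0,5
protein,ser_like,75.0,0.22,SER.h,1.0,3
protein,aromatic,147.2,0.12,E4P.h,1.0,4
protein,aromatic,147.2,0.12,PEP.c,2.0,3
fame,c16_acyl,256.4,1.0,ACA.h,8.0,2
dna,dnmp_residue,309.0,1.0,R5P.h,1.0,5
dna,dnmp_residue,309.0,1.0,OAA.m,1.0,4
rna,nmp_residue,321.0,1.0,R5P.h,1.0,5
rna,nmp_residue,321.0,1.0,OAA.m,1.0,4
chla,chlorophyll_a,893.5,1.0,AKG.m,8.0,5
chla,chlorophyll_a,893.5,1.0,PYR.c,5.0,3
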
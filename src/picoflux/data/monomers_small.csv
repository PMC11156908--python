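# Monomer/precursor stoichiometry for the minimal network (hexose storage
# mapped onto two triose phosphates; nucleotides onto sugar-phosphate
# surrogates).
macromolecule,monomer,monomer_mass,weight,precursor,coef,carbons
carbohydrate,anhydroglucose,162.14,1.0,TP,2.0,3
protein,ala_like,71.1,0.25,PYR,1.0,3
protein,asp_like,115.1,0.25,OAA,1.0,4
protein,glu_like,129.1,0.25,AKG,1.0,5
protein,ser_like,75.0,0.25,PGA,1.0,3
fame,c16_acyl,256.4,1.0,ACA,8.0,2
dna,dnmp_residue,309.0,1.0,TP,2.0,3
dna,dnmp_residue,309.0,1.0,PGA,1.25,3
rna,nmp_residue,321.0,1.0,TP,2.0,3
rna,nmp_residue,321.0,1.0,PGA,1.25,3
chla,chlorophyll_a,893.5,1.0,AKG,8.0,5
chla,chlorophyll_a,893.5,1.0,PYR,5.0,3
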
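# Strain biomass compositions (% ash-free dry weight) and specific growth
# rates under low light (LL) and high light (HL).  DNA, RNA and Chl a are
# assumed literature fractions; FAME, protein and carbohydrate are measured.
strain,light,growth_rate,growth_rate_sd,fame,fame_sd,protein,protein_sd,carbohydrate,carbohydrate_sd,dna,rna,chla
TG1,LL,0.110,0.038,18.8,0.2,55.9,,10.2,0.2,3.9,8.7,2.6
TG2,LL,0.079,0.039,21.6,1.3,49.0,,8.6,0.8,4.8,10.7,3.2
TG1-MYB99,LL,0.048,0.037,19.6,0.1,55.0,0.3,10.4,0.4,3.8,8.6,2.6
TG1,HL,0.220,0.079,11.8,0.2,29.9,0.1,44.9,0.3,3.4,7.66,2.3
TG2,HL,0.323,0.043,16.9,0.3,50.8,,16.0,1.1,3.9,8.6,2.6
TG1-MYB99,HL,0.254,0.041,9.5,0.3,21.0,3.0,56.1,2.7,3.4,7.6,2.3
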
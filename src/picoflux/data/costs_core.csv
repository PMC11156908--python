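# Cofactor costs per unit flux for the core scenario network (canonical
# stoichiometries).  Consumption positive, production negative; NADH is a
# separate currency.  The fix/red pair totals 3 ATP + 2 NADPH per net CO2
# fixed (1 ATP acceptor phosphorylation at fix; 1 ATP + 1 NADPH per PGA
# reduced, and RuBisCO makes two PGA per fix); the TK/TA regeneration lump
# is cofactor-neutral.  Lower glycolysis produces 2 ATP + 1 NADH per
# triose; malic enzyme produces NADPH.  Biomass-sink costs depend on the
# composition and are generated from the precursor demands at run time
# (see energetics.sink_cost_entries).
reaction,pathway,atp,nadph,nadh
src,uptake,0.0,0.0,0.0
fix,cbb,1.0,0.0,0.0
red,cbb,1.0,1.0,0.0
reg,cbb,0.0,0.0,0.0
ald,starch,0.0,0.0,0.0
pgm,starch,0.0,0.0,0.0
tpt,transport,0.0,0.0,0.0
pyk,glycolysis,-2.0,0.0,-1.0
ppc,anaplerosis,-1.0,0.0,-1.0
pdh,tca,0.0,0.0,-1.0
cs,tca,0.0,0.0,-1.0
akgsuc,tca,-1.0,0.0,-1.0
fum,tca,0.0,0.0,0.0
mdh,tca,0.0,0.0,-1.0
me,tca,0.0,-1.0,0.0
co2mc,transport,0.0,0.0,0.0
co2ch,transport,0.0,0.0,0.0
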
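site_id,plot_id,stage,group,dbh_cm,height_m,alive,grazing_damage
grazed,grazed-P1,adult,broadleaf,24.5,,True,False
grazed,grazed-P1,adult,motacu,36.0,12.1,True,False
grazed,grazed-P2,sapling,broadleaf,3.1,2.4,True,False
grazed,grazed-P2,sapling,motacu,,1.6,True,False
grazed,grazed-P3,sapling,broadleaf,4.0,3.5,True,True
grazed,grazed-P4,adult,other_palm,41.0,,True,False
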
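material_id,crystallinity,coated,primary_diameter_nm,primary_density,bet_ssa,suspension_diameter_nm,suspension_density,aerosol_diameter_nm,aerosol_density
NM105,80% anatase / 20% rutile,False,21,4.2,46.1,318,1.4,240,0.7
NM101,anatase,True,8,3.9,316,567,1.6,80,0.9
NM100,anatase,False,100,3.9,10,286,1.8,320,0.6
NM212,cubic cerianite,False,29,7.2,27,233,2.1,200,1.1
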
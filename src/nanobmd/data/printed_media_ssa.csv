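material_id,medium,printed_ssa
NM105,suspension,13.5
NM105,aerosol,37.7
NM101,suspension,6.7
NM101,aerosol,83.3
NM100,suspension,11.7
NM100,aerosol,31.3
NM212,suspension,12.5
NM212,aerosol,27.3
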
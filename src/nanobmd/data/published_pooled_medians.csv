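context_id,material_id,bmdl_median,bmdu_median
submerged_plate_24h,NM105,4.63,11.20
submerged_plate_24h,NM101,2.82,6.36
submerged_plate_24h,NM100,10.96,26.19
submerged_plate_24h,NM212,0.430,14.168
submerged_insert_3h21h,NM105,0.26,1.51
submerged_insert_3h21h,NM101,0.80,6.19
submerged_insert_3h21h,NM100,3.47,55.64
submerged_insert_3h21h,NM212,3.37,52.50
ali_insert_3h21h,NM105,0.061,0.82
ali_insert_3h21h,NM101,0.099,0.80
ali_insert_3h21h,NM100,0.045,0.90
ali_insert_3h21h,NM212,0.88,2.71
in_vivo_instillation,NM105,0.0007,0.075
in_vivo_instillation,NM101,0.0022,0.084
in_vivo_instillation,NM100,,
in_vivo_instillation,NM212,0.0000,0.074
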
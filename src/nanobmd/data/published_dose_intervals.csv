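context_id,material_id,endpoint,bmdl,bmdu
submerged_plate_24h,NM105,IL-1b,0.101,1.90
submerged_plate_24h,NM105,IL-6,4.50,11.11
submerged_plate_24h,NM105,IL-8,,
submerged_plate_24h,NM105,TNF-a,4.76,11.20
submerged_plate_24h,NM101,IL-1b,0.53,2.85
submerged_plate_24h,NM101,IL-6,4.86,10.47
submerged_plate_24h,NM101,IL-8,,
submerged_plate_24h,NM101,TNF-a,2.82,6.36
submerged_plate_24h,NM100,IL-1b,10.68,32.59
submerged_plate_24h,NM100,IL-6,,
submerged_plate_24h,NM100,IL-8,,
submerged_plate_24h,NM100,TNF-a,11.25,19.80
submerged_plate_24h,NM212,IL-1b,0.06,10.26
submerged_plate_24h,NM212,IL-6,,
submerged_plate_24h,NM212,IL-8,,
submerged_plate_24h,NM212,TNF-a,0.80,18.08
submerged_insert_3h21h,NM105,IL-1b,0.43,2.25
submerged_insert_3h21h,NM105,IL-6,0.20,1.36
submerged_insert_3h21h,NM105,IL-8,0.11,1.11
submerged_insert_3h21h,NM105,TNF-a,0.31,1.66
submerged_insert_3h21h,NM101,IL-1b,0.60,6.61
submerged_insert_3h21h,NM101,IL-6,1.28,8.17
submerged_insert_3h21h,NM101,IL-8,0.84,3.73
submerged_insert_3h21h,NM101,TNF-a,0.76,5.78
submerged_insert_3h21h,NM100,IL-1b,3.47,53.23
submerged_insert_3h21h,NM100,IL-6,,
submerged_insert_3h21h,NM100,IL-8,3.35,58.05
submerged_insert_3h21h,NM100,TNF-a,3.83,52.87
submerged_insert_3h21h,NM212,IL-1b,3.47,54.81
submerged_insert_3h21h,NM212,IL-6,2.30,50.25
submerged_insert_3h21h,NM212,IL-8,3.42,9.64
submerged_insert_3h21h,NM212,TNF-a,3.31,54.75
ali_insert_3h21h,NM105,IL-1b,0.051,0.80
ali_insert_3h21h,NM105,IL-6,0.037,0.81
ali_insert_3h21h,NM105,IL-8,0.078,0.83
ali_insert_3h21h,NM105,TNF-a,0.070,0.82
ali_insert_3h21h,NM101,IL-1b,0.061,0.74
ali_insert_3h21h,NM101,IL-6,0.089,0.77
ali_insert_3h21h,NM101,IL-8,1.13,11.87
ali_insert_3h21h,NM101,TNF-a,0.11,0.84
ali_insert_3h21h,NM100,IL-1b,0.006,0.91
ali_insert_3h21h,NM100,IL-6,0.012,0.88
ali_insert_3h21h,NM100,IL-8,0.078,0.90
ali_insert_3h21h,NM100,TNF-a,0.24,0.97
ali_insert_3h21h,NM212,IL-1b,0.63,2.61
ali_insert_3h21h,NM212,IL-6,0.88,2.71
ali_insert_3h21h,NM212,IL-8,,
ali_insert_3h21h,NM212,TNF-a,,
in_vivo_instillation,NM105,IL-1b,0.0011,0.067
in_vivo_instillation,NM105,IL-6,0.00069,0.13
in_vivo_instillation,NM105,IL-8,0.00019,0.084
in_vivo_instillation,NM105,TNF-a,0.00075,0.0091
in_vivo_instillation,NM101,IL-1b,,
in_vivo_instillation,NM101,IL-6,0.0044,0.086
in_vivo_instillation,NM101,IL-8,,
in_vivo_instillation,NM101,TNF-a,0.000,0.082
in_vivo_instillation,NM100,IL-1b,,
in_vivo_instillation,NM100,IL-6,,
in_vivo_instillation,NM100,IL-8,,
in_vivo_instillation,NM100,TNF-a,,
in_vivo_instillation,NM212,IL-1b,,
in_vivo_instillation,NM212,IL-6,0.000,0.019
in_vivo_instillation,NM212,IL-8,0.0033,0.082
in_vivo_instillation,NM212,TNF-a,0.000,0.074
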
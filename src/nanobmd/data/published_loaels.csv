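context_id,loael_ug_per_cm2
in_vivo_instillation,0.1
ali_insert_3h21h,1
submerged_insert_3h21h,3
submerged_plate_24h,10
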
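entry_id	label
core_A	core
core_ACP	core
core_AT	core
core_C	core
core_CDPS	core
core_CMeT	core
core_CS	core
core_DH	core
core_DMAT	core
core_E	core
core_ER	core
core_FAS_alpha	core
core_FAS_beta	core
core_GGPPS	core
core_GT	core
core_KR	core
core_KS	core
core_LSS	core
core_PT	core
core_PTase	core
core_R	core
core_SAT	core
core_SHC	core
core_T	core
core_TC	core
core_TE	core
core_typeIII	core
core_ripp_precursor	core
tail_p450	tailoring
tail_fmo	tailoring
tail_omt	tailoring
tail_ktr	tailoring
tail_acyl	tailoring
tail_oxred	tailoring
tail_halo	tailoring
tail_hydrolase	tailoring
reg_zn2c6	regulatory
reg_bzip	regulatory
reg_c2h2	regulatory
trans_mfs	transport
trans_abc	transport
trans_mate	transport
res_efflux	resistance
res_target	resistance
hk_actin	housekeeping
hk_tubulin	housekeeping
hk_ef1a	housekeeping
hk_gapdh	housekeeping
hk_rps	housekeeping
hk_histone	housekeeping
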
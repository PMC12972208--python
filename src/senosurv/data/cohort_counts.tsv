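cohort	covariate	category	count
OS	total	total	1406
OS	histology	LUAD	670
OS	histology	LUSC	526
OS	histology	large-cell	52
OS	histology	LCNEC	56
OS	stage_T	1	220
OS	stage_T	2	190
OS	stage_T	3	33
OS	stage_T	4	21
OS	stage_N	0	324
OS	stage_N	1	104
OS	stage_N	2	30
OS	stage_M	0	459
OS	stage_M	1	8
OS	sex	female	476
OS	sex	male	819
OS	smoking	never	143
OS	smoking	smoker	330
FP	total	total	870
FP	histology	LUAD	526
FP	histology	LUSC	220
FP	histology	large-cell	10
FP	histology	LCNEC	44
FP	stage_T	1	212
FP	stage_T	2	185
FP	stage_T	3	29
FP	stage_T	4	20
FP	stage_N	0	313
FP	stage_N	1	100
FP	stage_N	2	27
FP	stage_M	0	442
FP	stage_M	1	6
FP	sex	female	294
FP	sex	male	576
FP	smoking	never	141
FP	smoking	smoker	297
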
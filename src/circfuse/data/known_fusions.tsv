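# Bundled known-fusion gene pair catalogue (gene5	gene3	source)
# Small curated starter list of recurrent cancer fusions; users supply their own
# table for real analyses. Symbols must match the reference FASTA record ids.
EML4	ALK	lung_adenocarcinoma
NPM1	ALK	anaplastic_large_cell_lymphoma
EWSR1	FLI1	ewing_sarcoma
EWSR1	ATF1	clear_cell_sarcoma
KMT2A	MLLT3	acute_myeloid_leukemia
KMT2A	AFF1	acute_lymphoblastic_leukemia
PML	RARA	acute_promyelocytic_leukemia
BCR	ABL1	chronic_myeloid_leukemia
ETV6	RUNX1	acute_lymphoblastic_leukemia
NTRK3	ETV6	secretory_breast_carcinoma
TMPRSS2	ERG	prostate_cancer
TMPRSS2	ETV1	prostate_cancer
CD74	ROS1	lung_adenocarcinoma
SLC34A2	ROS1	lung_adenocarcinoma
HOOK3	RET	papillary_thyroid_carcinoma
CCDC6	RET	papillary_thyroid_carcinoma
AKAP9	BRAF	papillary_thyroid_carcinoma
BRD4	NUTM1	nut_midline_carcinoma
FGFR3	TACC3	glioblastoma
DNAJB1	PRKACA	fibrolamellar_carcinoma
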
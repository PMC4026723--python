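matrix_family	site_id	gene	branch
C2H2 zinc finger transcription factors 2	cg27318281	C18ORF37	human_terminal
C2H2 zinc finger transcription factors 2	cg19047670	CCND1	human_chimp
C2H2 zinc finger transcription factors 2	cg00962459	PROKR1	ape
C2H2 zinc finger transcription factors 2	cg03570766	CATSPER1	ape
C2H2 zinc finger transcription factors 2	cg12439773	SLC22A6	theria
RNA polymerase II transcription factor II B	cg10498097	MGC50811	ape
RNA polymerase II transcription factor II B	cg04033774	GPSM2	primate
RNA polymerase II transcription factor II B	cg20318748	NANP	primate
RNA polymerase II transcription factor II B	cg24673765	HSPB6	placental
Pleomorphic adenoma gene	cg06445611	GABRR2	human_chimp
Pleomorphic adenoma gene	cg24505375	AMAC1L2	human_chimp
Pleomorphic adenoma gene	cg13316424	CIZ1	primate
Pleomorphic adenoma gene	cg21835643	RBPSUHL	theria
NeuroD, beta2, HLH domain	cg04587829	FN3K	ape
NeuroD, beta2, HLH domain	cg00427635	TBC1D21	primate
TALE homeodomain class recognizing TG motifs	cg19531130	ANGPTL5	human_chimp
TALE homeodomain class recognizing TG motifs	cg01813965	C16orf50	ape
Cart-1 (cartilage homeoprotein 1)	cg13316424	CIZ1	primate
Human and murine ETS1 factors	cg06084117	PLXNA4B	human_chimp
Human and murine ETS1 factors	cg20792833	PTPRCAP	placental
Vertebrate SNAD family of transcription factors	cg13471990	ENTPD1	ape
Par/bZIP family	cg25293251	GOLGA5	human_terminal
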
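accession	name	organism	target_class
APH07629	orsellinic acid synthase PKS1	Agaricomycetes sp.	typeI_PKS
XP_960427	chalcone synthase	Neurospora crassa	typeIII_PKS
S3DQP3	A1 domain of nonribosomal peptide synthetase GloA	Glarea lozoyensis	NRPS_family
AHY23922	1,8-cineole synthase	Hypoxylon sp.	terpene
AWM95795	humulene synthase Asr6	Sarocladium sp.	terpene
Q6WP50	presilphiperfolan-8-beta-ol synthase Bot2	Botrytis cinerea	terpene
QOE88883	brasilane synthase BraA	Annulohypoxylon truncatum	terpene
C9K2Q3	fusicoccadiene synthase	Alternaria brassicicola	terpene
A0A1B4XBG5	cycloaraneosene synthase SdnA	Sordaria araneosa	terpene
B2DBF1	copalyl diphosphate synthase	Diaporthe amygdali	terpene
P38604	lanosterol synthase Erg7	Saccharomyces cerevisiae	terpene
QOV03404	citrate synthase SpoE	Hypomontagnella monticulosa	alkyl_citrate
D4D449	tryptophan dimethylallyltransferase	Trichophyton verrucosum	alkaloid_DMAT
AMR44282	phomopsin precursor PhomA	Diaporthe leptostromiformis	RiPP_precursor
OphMA	omphalotin precursor OphMA	Omphalotus olearius	RiPP_precursor
ACB30126	epichloecyclin precursor GigA	Epichloe festucae	RiPP_precursor
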
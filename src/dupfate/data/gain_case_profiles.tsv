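duplication	gene	putative_function	ps	bs_mnm	AM	AP	AO	E0	E1A	E1K	E2A	E2K	E3A	E3K	H	HP	HR2	HR4	LP	G	SG	B
duplication_159	LOC103311559	Uncharacterized	0	0	0	0	0	0	0	0	0	0	0	0	NA	0	0	0	0	0	NA	0
duplication_159	LOC100166252	PiggyBac transposable element-derived protein 4-like	1	0	NA	NA	NA	NA	NA	NA	NA	NA	1	1	NA	NA	0	0	0	1	NA	NA
duplication_213	LOC100570324	Uncharacterized	0	0	1	0	NA	NA	1	1	NA	1	NA	NA	0	1	NA	0	0	NA	NA	NA
duplication_213	LOC100574933	PAX-interacting protein 1-like	1	0	1	1	1	1	1	1	1	1	1	1	NA	NA	1	1	1	NA	1	1
duplication_288	LOC100572588	Uncharacterized	0	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	1	1	1	1
duplication_288	LOC103308356	Uncharacterized	1	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1	NA	1	1	1
duplication_322	LOC107883251	Uncharacterized	0	0	0	NA	NA	1	NA	1	1	1	1	1	1	NA	1	1	NA	1	1	1
duplication_322	LOC107883068	Uncharacterized	1	1	1	1	NA	1	1	1	1	1	1	NA	1	1	1	1	1	1	1	1
duplication_340	LOC103310866	Uncharacterized RING finger protein C32D5.10-like	0	0	0	0	0	NA	0	0	0	0	0	0	0	0	0	0	0	NA	0	0
duplication_340	LOC100571229	E3 ubiquitin-protein ligase Topors-like	1	0	1	1	1	1	1	1	1	1	1	1	0	NA	NA	0	1	NA	NA	1
duplication_397	LOC100162340	Dynein heavy chain 1, axonemal	0	0	1	0	0	0	0	0	0	NA	0	0	0	0	0	NA	0	NA	0	0
duplication_397	LOC107882216	Dynein heavy chain 1, axonemal-like	1	0	0	NA	1	0	0	0	NA	0	NA	0	NA	1	0	NA	0	NA	NA	NA
duplication_4	LOC100568916	Uncharacterized	0	0	1	NA	1	1	1	1	1	1	1	1	NA	NA	0	0	NA	NA	NA	NA
duplication_4	LOC100160128	26S proteasome non-ATPase regulatory subunit 12-like	1	0	1	1	1	1	1	1	1	1	1	1	NA	1	1	1	1	NA	NA	1
duplication_460	LOC107882168	Zinc finger protein 134-like	0	0	0	0	NA	0	NA	NA	0	0	NA	NA	0	0	0	0	0	NA	NA	0
duplication_460	LOC103310004	Zinc finger protein 134-like	1	0	1	0	1	NA	NA	0	0	NA	0	0	0	0	0	0	0	NA	NA	0
duplication_489	LOC107882711	Uncharacterized	0	0	NA	1	1	1	1	1	1	1	1	1	NA	1	1	1	0	1	NA	1
duplication_489	LOC100162929	Uncharacterized	1	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
duplication_576	LOC100569858	Uncharacterized	0	0	1	0	0	NA	NA	0	0	0	0	0	NA	0	0	0	0	NA	NA	0
duplication_576	LOC100574180	Uncharacterized	1	0	1	0	0	NA	NA	0	NA	NA	0	NA	0	NA	1	NA	0	1	1	0
duplication_633	LOC103309550	Zinc finger MYM-type protein 1-like	0	0	0	0	0	0	0	0	0	0	0	0	NA	0	0	0	0	NA	NA	0
duplication_633	LOC103307955	Zinc finger MYM-type protein 1-like	1	0	0	NA	NA	0	NA	0	0	NA	0	0	NA	NA	NA	0	0	NA	NA	1
duplication_663	LOC107884962	Uncharacterized	0	0	0	0	0	1	NA	1	NA	NA	NA	1	NA	0	0	0	0	1	1	NA
duplication_663	LOC100570263	Uncharacterized	1	0	NA	1	1	1	1	1	1	1	1	1	NA	1	NA	0	1	NA	1	1
duplication_693	LOC100165085	Uncharacterized	0	0	1	0	0	NA	0	NA	0	NA	0	0	NA	0	NA	NA	NA	NA	NA	1
duplication_693	LOC100165046	Dynein heavy chain 7, axonemal-like	1	1	NA	1	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
duplication_795	LOC107882727	Sialin-like	0	0	0	NA	0	0	0	0	0	0	0	0	NA	1	1	1	1	NA	NA	NA
duplication_795	LOC100164217	Putative inorganic phosphate cotransporter	1	0	1	1	1	NA	1	1	1	1	1	1	1	1	1	1	1	1	1	1
duplication_840	LOC100571978	Uncharacterized	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	0
duplication_840	LOC107884413	Uncharacterized	1	0	0	0	0	0	NA	NA	0	NA	NA	0	NA	NA	1	1	0	NA	NA	0
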
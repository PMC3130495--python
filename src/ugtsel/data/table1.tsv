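id	label	acceptor	organism	accession	class
1	CsF3GT	Flavonol	Citrus sinensis	AAS00612	3
2	RhA53GT	Anthocyanidin	Rosa hybrida	BAD99560.1	5, 3
3	VvGT	Anthocyanidin/Flavonol	Vitis vinifera	O22304	3
4	IhA3GT	Anthocyanidin	Iris hollandica	Q5KTF3	3
5	DcC2′GT	Chalcone	Dianthus caryophyllus	Q60FE8	2′
6	DcF3GT1	Anthocyanidin/Flavonol	Dianthus caryophyllus	Q60FF0	3
7	DcF3GT2	Anthocyanidin/Flavonol	Dianthus caryophyllus	Q60FF2	3
8	GtA3GT	Anthocyanidin/Flavonol	Gentiana triflora	Q96493	3
9	CuLGT	Limonoid	Citrus unshiu	Q9MB73	NA
10	DbB5GT	Flavone/Flavonol*	Dorotheanthus bellidiformis	Q9SMG6	4′
11	SbF7GT	Flavone	Scutellaria baicalensis	Q9SXF2	7
12	VhA5GT	Anthocyandin	Verbena hybrida	Q9ZR25	5
13	PfA5GT	Anthocyandin	Perilla frutescens	Q9ZR27	5
14	At7GT	Flavanone	Arabidopsis thaliana	NP_567955	7
15	BvF4′7GT	Flavone/Flavonol	Beta vulgaris	AAS94329.1	4′, 7
16	BvF37GT	Flavonol	Beta vulgaris	AAS94330.1	3, 7
17	GtA3′GT	Anthocyandin	Gentiana triflora	BAC54092	3′
18	GmF7GT	Isoflavone	Glycine max	BAF64416	7
19	NtF7GT	Flavonol	Nicotiana tabacum	BAB88935.1	7
20	OsF3GT	Flavonol	Oryza sativa	NP_001044170	3
21	PhA5GT	Anthocyandin	Petunia hybrida	BAA89009.1	5
22	PhA3GT	Anthocyandin	Petunia hybrida	BAA89008.1	3
23	UGT71G1	Flavonol*	Medicago truncatula	Q5IFH7	3′
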
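# organism=Muraenesox cinereus
# accession=MT571331
# genome_length=17673
# circular=true
# note=intergenic column is the published value for the gap upstream of each feature; recompute from coordinates and cross-check before use
name	class	start	end	strand	start_codon	stop_codon	anticodon	intergenic
trnF	tRNA	1	72	H	.	.	GAA	0
12S	rRNA	73	1034	H	.	.	.	0
trnV	tRNA	1035	1104	H	.	.	TAC	0
16S	rRNA	1105	2810	H	.	.	.	0
trnL1	tRNA	2811	2886	H	.	.	TAA	0
ND1	PCG	2887	3855	H	ATG	TAA	.	0
trnI	tRNA	3863	3934	H	.	.	GAT	7
trnQ	tRNA	3935	4005	L	.	.	.	0
trnM	tRNA	4005	4074	H	.	.	CAT	-1
ND2	PCG	4075	5118	H	ATG	TAG	.	0
trnW	tRNA	5117	5186	H	.	.	TCA	-2
trnA	tRNA	5188	5256	L	.	.	TGC	1
trnN	tRNA	5258	5330	L	.	.	GTT	1
OL	OL	5331	5369	H	.	.	.	-7
trnC	tRNA	5381	5446	L	.	.	GCA	7
trnY	tRNA	5447	5517	L	.	.	GCA	0
COI	PCG	5519	7121	H	GTG	TAA	.	1
trnS1	tRNA	7122	7192	L	.	.	TGA	0
trnD	tRNA	7198	7265	H	.	.	GTC	5
COII	PCG	7269	7959	H	ATG	T-	.	3
trnK	tRNA	7960	8034	H	.	.	TTT	0
ATP8	PCG	8036	8203	H	ATG	TAA	.	1
ATP6	PCG	8194	8877	H	ATG	TAA	.	-10
COIII	PCG	8877	9662	H	ATG	TAA	.	-1
trnG	tRNA	9662	9731	H	.	.	TCC	-1
ND3	PCG	9732	10082	H	ATG	TAG	.	0
trnR	tRNA	10081	10150	H	.	.	TCG	-2
ND4L	PCG	10151	10447	H	ATG	TAA	.	0
ND4	PCG	10441	11821	H	ATG	T-	.	-7
trnH	tRNA	11822	11890	H	.	.	GTG	0
trnS2	tRNA	11891	11961	H	.	.	GCT	0
trnL2	tRNA	11962	12033	H	.	.	TAG	0
ND5	PCG	12034	13890	H	ATG	TAA	.	0
Cytb	PCG	13926	15065	H	ATG	AGA	.	35
trnT	tRNA	15070	15141	H	.	.	TGT	4
CR1	CR	15142	16043	H	.	.	.	0
ND6	PCG	16044	16559	L	ATG	AGG	.	0
trnE	tRNA	16561	16629	L	.	.	TTC	1
trnP	tRNA	16653	16729	L	.	.	TGG	23
CR2	CR	16730	17673	H	.	.	.	0
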
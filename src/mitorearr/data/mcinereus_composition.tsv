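# organism=Muraenesox cinereus
# accession=MT571331
# note=published per-region base percentages and skews; skews are recomputable from the percentages
region	pct_a	pct_t	pct_c	pct_g	at_percent	at_skew	gc_skew	length
Mitogenome	32.1	27.6	23.8	16.6	59.7	0.076	-0.179	17673
ND1	28.8	28.6	26.9	15.7	57.4	0.004	-0.264	969
ND2	34.9	28.7	24.0	12.4	63.6	0.096	-0.321	1044
COI	26.4	31.1	24.0	18.5	57.5	-0.082	-0.128	1603
COII	30.1	28.5	24.5	16.9	58.6	0.027	-0.182	691
ATP8	35.1	30.4	25.6	8.9	65.5	0.073	-0.483	168
ATP6	30.3	32.6	24.4	12.7	62.9	-0.037	-0.315	684
COIII	28.1	30.7	23.9	17.3	58.8	-0.043	-0.160	786
ND3	28.2	33.3	24.8	13.7	61.5	-0.083	-0.289	351
ND4	31.3	29.8	23.6	15.4	61.0	0.025	-0.212	1381
ND4L	25.9	27.6	29.3	17.2	53.5	-0.031	-0.261	297
ND5	32.5	28.4	25.5	13.6	60.9	0.067	-0.304	1857
Cytb	28.7	27.9	26.4	17.0	56.6	0.014	-0.216	1140
ND6	44.6	14.1	28.3	13.0	58.7	0.520	-0.370	516
tRNA	32.0	25.3	23.1	19.6	57.3	0.116	-0.081	1564
rRNA	35.1	21.7	22.6	20.6	56.7	0.236	-0.047	2668
CR	36.2	30.1	18.0	15.8	66.3	0.092	-0.066	1846
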
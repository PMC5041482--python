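# Baseline S. cerevisiae-like codon usage (occurrences per 1000 codons).
# Drives the synthetic-data generator's amino-acid and synonymous-codon draws.
codon	aa	per_1000
AAA	K	41.9
AAC	N	24.8
AAG	K	30.8
AAT	N	35.7
ACA	T	17.8
ACC	T	12.7
ACG	T	8.0
ACT	T	20.3
AGA	R	21.3
AGC	S	9.8
AGG	R	9.2
AGT	S	14.2
ATA	I	17.8
ATC	I	17.2
ATG	M	20.9
ATT	I	30.1
CAA	Q	27.3
CAC	H	7.8
CAG	Q	12.1
CAT	H	13.6
CCA	P	18.3
CCC	P	6.8
CCG	P	5.3
CCT	P	13.5
CGA	R	3.0
CGC	R	2.6
CGG	R	1.7
CGT	R	6.4
CTA	L	13.4
CTC	L	5.4
CTG	L	10.5
CTT	L	12.3
GAA	E	45.6
GAC	D	20.2
GAG	E	19.2
GAT	D	37.6
GCA	A	16.2
GCC	A	12.6
GCG	A	6.2
GCT	A	21.2
GGA	G	10.9
GGC	G	9.8
GGG	G	6.0
GGT	G	23.9
GTA	V	11.8
GTC	V	11.8
GTG	V	10.8
GTT	V	22.1
TAA	*	1.1
TAC	Y	14.8
TAG	*	0.5
TAT	Y	18.8
TCA	S	18.7
TCC	S	14.2
TCG	S	8.6
TCT	S	23.5
TGA	*	0.7
TGC	C	4.8
TGG	W	10.4
TGT	C	8.1
TTA	L	26.2
TTC	F	18.4
TTG	L	27.2
TTT	F	26.1
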
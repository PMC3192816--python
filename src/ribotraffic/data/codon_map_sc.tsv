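codon	species_id
GCT	1
GCC	1
GCA	2
GCG	2
CGT	3
CGC	3
CGA	3
CGG	4
AGG	5
AGA	6
AAC	7
AAT	7
GAC	8
GAT	8
TGC	9
TGT	9
CAG	10
CAA	11
GAG	12
GAA	13
GGG	14
GGC	15
GGT	15
GGA	16
CAC	17
CAT	17
ATT	18
ATC	18
ATA	19
TTG	20
CTC	21
CTT	21
TTA	22
CTA	23
CTG	23
AAG	24
AAA	25
ATG	26
TTC	27
TTT	27
CCT	28
CCC	28
CCA	29
CCG	29
TCT	30
TCC	30
TCG	31
AGC	32
AGT	32
TCA	33
ACT	34
ACC	34
ACG	35
ACA	36
TGG	37
TAC	38
TAT	38
GTT	39
GTC	39
GTG	40
GTA	41
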
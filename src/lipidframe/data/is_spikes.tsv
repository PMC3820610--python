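class	standard_label	spike_pmol
CE	CE 19:0 (IS)	54
TAG	TAG 17:1/17:1/17:1	35
DAG	DAG 19:0/19:0	35
LPA	LPA O-16:0	26
LPA O-	LPA O-16:0	26
PA	PA 17:0/14:1	35
LPS	LPS 17:1 (IS)	25
PS	PS 17:0/20:4	13
PE O-	PE O-20:0/O-20:0	50
PE	PE O-20:0/O-20:0	50
LPC	LPC O-17:0	30
LPC O-	LPC O-17:0	30
LPE	LPC O-17:0	30
PC	PC 18:3/18:3	137
PC O-	PC 18:3/18:3	137
PI	PI 17:0/20:4	35
LPI	PI 17:0/20:4	35
PG	PG 17:0/17:0	30
Cer	Cer 18:1;2/17:0;0	55
SM	SM 18:1;2/17:0;0	69
HexCer	HexCer 18:1;2/12:0;0	49
SHexCer	SHexCer 18:1;2/12:0;0	28
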
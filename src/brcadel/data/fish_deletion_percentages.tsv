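sample_id	brca_status	chr13	chr14
52	BRCA2	84	89
86	BRCA2	90	86
106	BRCA2	100	87
133	BRCA2	93	89
A	BRCA2	84	83
B	BRCA2	100	0
C	BRCA2	87	7
D	BRCA2	100	62
E	BRCA2	100	73
16	BRCAX	0	0
F	BRCAX	0	2
G	BRCAX	0	0
H	BRCAX	100	100
I	BRCAX	4	0
J	BRCAX	0	0
K	BRCAX	2	0
L	BRCAX	7	3
M	BRCAX	10	0
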
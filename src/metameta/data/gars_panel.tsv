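symbol	variant	risk_allele
DRD1	rs4532	G
DRD2	rs1800497	A1
DRD3	rs6280	C
DRD4	rs1800955	C
SLC6A3	3'-UTR 40bp VNTR	A9
COMT	rs4680	G
OPRM1	rs1799971	G
GABRB3	CA repeat	181
MAOA	3' 30bp VNTR	4R
SLC6A4	rs25531	S'
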
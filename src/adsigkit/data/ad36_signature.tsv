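# 36-gene atopic-dermatitis signature: gene symbol, weight (+1 up / -1 down in human lesional skin)
AQP3	1
BTC	-1
CBX7	-1
DSC2	1
FABP5	1
FAM117A	-1
FRZB	-1
FSCN1	1
GALNT6	1
GCH1	1
HBEGF	1
ISG15	1
KLK6	1
KRT15	-1
KRT16	1
KRT6A	1
KRT6B	1
MAPK6	1
NCAPG	1
OAS3	1
PIK3C2G	-1
RAB31	1
RYR1	-1
S100A8	1
S100A9	1
SELE	1
SLC7A5	1
SPRR1A	1
SPRR1B	1
TNC	1
TNNI2	-1
TUBB2A	1
TUBB3	1
UPP1	1
VIPR1	-1
ZWILCH	1
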
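protein	complex
KMT2C	MLL3/MLL4
KMT2D	MLL3/MLL4
PAXIP1	MLL3/MLL4
NCOA6	MLL3/MLL4
PAGR1	MLL3/MLL4
ASH2L	MLL3/MLL4
RBBP5	MLL3/MLL4
WDR5	MLL3/MLL4
DPY30	MLL3/MLL4
KDM6A	MLL3/MLL4
BAP1	PR-DUB
MBD6	PR-DUB
KDM1B	PR-DUB
ASXL2	PR-DUB
DNTTIP1	MiDAC
ELMSAN1	MiDAC
HDAC1	MiDAC
HDAC2	MiDAC
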
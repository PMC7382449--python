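gene	gtex	biogps	cgap	hbt
ACIN1	1	1	1	1
LRRK1	1	1	1	1
DIAPH3	1	1	1	1
LIMCH1	1	1	1	1
NEK4	1	1	1	1
PCLO	1	1	1	1
ACCS	1	1	1	0
CRELD2	1	1	1	1
THBS4	1	1	1	1
PDHA1	1	1	1	1
PTP4A3	1	1	1	1
TMEM183A	1	1	1	1
PPFIBP1	1	1	1	1
PTCH1	1	1	1	1
ZFHX3	1	1	1	1
KMT2A	1	1	1	1
NLE1	1	1	1	1
ACSS3	1	1	1	1
SYNE1	1	1	1	1
NBAS	1	1	1	1
DNAH1	1	1	1	1
PLCB2	1	1	1	1
SRRM2	1	1	1	1
TLK2	1	1	1	1
SLC9A9	1	1	1	1
GNB4	1	1	1	1
SPAG5	1	1	1	1
DOPEY2	1	1	1	1
HEATR1	1	1	1	1
PSRC1	1	1	1	1
KIF21A	1	1	1	1
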
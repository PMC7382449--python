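GLUTAMATERGIC_SYNAPSE	toy	PCLO	PLCB2	GNB4	SLC9A9	SYNE1	PTCH1	THBS4	DCY000	DCY001	DCY002	DCY003	DCY004	DCY005	DCY006	DCY007
CYTOSKELETON_ORGANIZATION	toy	DIAPH3	LIMCH1	SPAG5	KIF21A	DNAH1	DCY008	DCY009	DCY010	DCY011	DCY012	DCY013	DCY014	DCY015	DCY016	DCY017	DCY018	DCY019	DCY020	DCY021	DCY022
CHROMATIN_AND_DNA_REPAIR	toy	ACIN1	NEK4	PSRC1	TLK2	DCY023	DCY024	DCY025	DCY026	DCY027	DCY028	DCY029	DCY030	DCY031	DCY032	DCY033	DCY034	DCY035	DCY036	DCY037	DCY038
TRANSCRIPTION_REGULATION	toy	KMT2A	ZFHX3	DCY039	DCY040	DCY041	DCY042	DCY043	DCY044	DCY045	DCY046	DCY047	DCY048	DCY049	DCY050
METABOLIC_PROCESS	toy	PDHA1	ACSS3	ACCS	DCY051	DCY052	DCY053	DCY054	DCY055	DCY056	DCY057	DCY058	DCY059	DCY060	DCY061	DCY062	DCY063	DCY064	DCY065	DCY066	DCY067	DCY068	DCY069	DCY070	DCY071	DCY072	DCY073	DCY074	DCY075
INTRACELLULAR_TRAFFICKING	toy	NBAS	LRRK1	CRELD2	PPFIBP1	DOPEY2	PTP4A3	TMEM183A	DCY076	DCY077	DCY078	DCY079	DCY080	DCY081	DCY082	DCY083	DCY084	DCY085	DCY086	DCY087	DCY088	DCY089	DCY090	DCY091	DCY092	DCY093	DCY094	DCY095	DCY096	DCY097	DCY098	DCY099	DCY100	DCY101	DCY102	DCY103	DCY104	DCY105	DCY106	DCY107	DCY108	DCY109	DCY110	DCY111	DCY112	DCY113	DCY114	DCY115
RNA_PROCESSING	toy	SRRM2	HEATR1	NLE1	DCY116	DCY117	DCY118	DCY119	DCY120	DCY121	DCY122	DCY123	DCY124	DCY125	DCY126	DCY127	DCY128	DCY129	DCY130	DCY131	DCY132	DCY133	DCY134	DCY135	DCY136	DCY137	DCY138	DCY139	DCY140
IMMUNE_RESPONSE	toy	DCY141	DCY142	DCY143	DCY144	DCY145	DCY146	DCY147	DCY148	DCY149	DCY150	DCY151	DCY152	DCY153	DCY154	DCY155	DCY156	DCY157	DCY158	DCY159	DCY160
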
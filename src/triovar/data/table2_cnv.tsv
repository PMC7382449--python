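family	member	chrom	start	end	size_kbp	state	zygosity	gene_of_interest
F5	F5_P	22	51073379	51197838	124.459	loss	het	SHANK3
F5	F5_US1	22	51073379	51197725	124.346	loss	het	SHANK3
F5	F5_US2	22	51130158	51183869	53.711	loss	het	SHANK3
F5	F5_UM	22	51073379	51197838	124.459	loss	het	SHANK3
F5	F5_UF	22	51073265	51197838	124.573	loss	het	SHANK3
F10	F10_P	9	139252010	139435356	183.346	gain		NOTCH1
F10	F10_UM	9	139114307	139435356	321.049	gain		NOTCH1
F15	F15_P	22	51127896	51197725	69.829	loss	het	SHANK3
F17	F17_P	9	139375930	139435356	59.426	gain		NOTCH1
F17	F17_US2	9	139053501	139654647	601.146	gain		NOTCH1
F17	F17_UF	9	139056879	139431947	375.068	gain		NOTCH1
F19	F19_P	14	79342954	79397500	54.546	loss	het	NRXN3
F19	F19_US1	14	79342954	79401388	58.434	loss	het	NRXN3
F19	F19_US2	14	79342954	79397500	54.546	loss	het	NRXN3
F19	F19_UM	14	79342954	79401337	58.383	loss	het	NRXN3
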
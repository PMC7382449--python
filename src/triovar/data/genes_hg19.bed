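chr22	51113069	51171640	SHANK3
chr9	139388895	139440238	NOTCH1
chr14	78870073	80334633	NRXN3
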
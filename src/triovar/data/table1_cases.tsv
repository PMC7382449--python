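family	role	sex	age_years	suspected	dna_available
F1	proband	male	17	0	1
F1	affected_sibling	male	19	0	1
F1	affected_sibling	male	13	0	1
F1	affected_sibling	male	7	0	1
F2	proband	male	8	0	1
F5	proband	male	11	0	1
F7	proband	male	16	0	1
F7	affected_sibling	male	17	0	1
F9	proband	male	13	0	1
F9	affected_sibling	female	17	0	1
F10	proband	female	16	0	1
F10	affected_sibling	male	21	0	1
F12	proband	female	11	0	1
F14	proband	male	9	0	1
F15	proband	female	8	0	1
F16	proband	male	6	0	1
F17	proband	female	12	0	1
F17	affected_sibling	male	8	0	1
F19	proband	male	10	0	1
F19	affected_father	male	NA	0	1
F21	proband	male	10	0	1
F21	affected_sibling	female	NA	0	0
F22	proband	male	15	0	1
F22	affected_sibling	male	14	0	1
F22	affected_sibling	male	10	0	1
F22	affected_sibling	male	5	0	1
F24	proband	male	9	0	1
F25	proband	male	16	0	1
F25	affected_sibling	male	14	0	1
F25	affected_sibling	male	13	0	1
F25	affected_sibling	female	4	1	1
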
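#family	sample	father	mother	sex	phenotype	role	age	status
F1	F1_UF	0	0	1	1	father	NA	unaffected
F1	F1_UM	0	0	2	1	mother	NA	unaffected
F1	F1_P	F1_UF	F1_UM	1	2	proband	17	affected
F1	F1_AS1	F1_UF	F1_UM	1	2	sibling	19	affected
F1	F1_AS2	F1_UF	F1_UM	1	2	sibling	13	affected
F1	F1_AS3	F1_UF	F1_UM	1	2	sibling	7	affected
F1	F1_US1	F1_UF	F1_UM	2	1	sibling	NA	unaffected
F1	F1_US2	F1_UF	F1_UM	1	1	sibling	NA	unaffected
F2	F2_UF	0	0	1	1	father	NA	unaffected
F2	F2_UM	0	0	2	1	mother	NA	unaffected
F2	F2_P	F2_UF	F2_UM	1	2	proband	8	affected
F5	F5_UF	0	0	1	1	father	NA	unaffected
F5	F5_UM	0	0	2	1	mother	NA	unaffected
F5	F5_P	F5_UF	F5_UM	1	2	proband	11	affected
F5	F5_US1	F5_UF	F5_UM	2	1	sibling	NA	unaffected
F5	F5_US2	F5_UF	F5_UM	1	1	sibling	NA	unaffected
F7	F7_UF	0	0	1	1	father	NA	unaffected
F7	F7_UM	0	0	2	1	mother	NA	unaffected
F7	F7_P	F7_UF	F7_UM	1	2	proband	16	affected
F7	F7_AS1	F7_UF	F7_UM	1	2	sibling	17	affected
F9	F9_UF	0	0	1	1	father	NA	unaffected
F9	F9_UM	0	0	2	1	mother	NA	unaffected
F9	F9_P	F9_UF	F9_UM	1	2	proband	13	affected
F9	F9_AS1	F9_UF	F9_UM	2	2	sibling	17	affected
F10	F10_UF	0	0	1	1	father	NA	unaffected
F10	F10_UM	0	0	2	1	mother	NA	unaffected
F10	F10_P	F10_UF	F10_UM	2	2	proband	16	affected
F10	F10_AS1	F10_UF	F10_UM	1	2	sibling	21	affected
F12	F12_UF	0	0	1	1	father	NA	unaffected
F12	F12_UM	0	0	2	1	mother	NA	unaffected
F12	F12_P	F12_UF	F12_UM	2	2	proband	11	affected
F14	F14_UF	0	0	1	1	father	NA	unaffected
F14	F14_UM	0	0	2	1	mother	NA	unaffected
F14	F14_P	F14_UF	F14_UM	1	2	proband	9	affected
F14	F14_US1	F14_UF	F14_UM	2	1	sibling	NA	unaffected
F14	F14_US2	F14_UF	F14_UM	1	1	sibling	NA	unaffected
F15	F15_UF	0	0	1	1	father	NA	unaffected
F15	F15_UM	0	0	2	1	mother	NA	unaffected
F15	F15_P	F15_UF	F15_UM	2	2	proband	8	affected
F15	F15_US1	F15_UF	F15_UM	1	1	sibling	NA	unaffected
F15	F15_US2	F15_UF	F15_UM	2	1	sibling	NA	unaffected
F15	F15_US3	F15_UF	F15_UM	2	1	sibling	NA	unaffected
F16	F16_UF	0	0	1	1	father	NA	unaffected
F16	F16_UM	0	0	2	1	mother	NA	unaffected
F16	F16_P	F16_UF	F16_UM	1	2	proband	6	affected
F16	F16_US1	F16_UF	F16_UM	1	1	sibling	NA	unaffected
F17	F17_UF	0	0	1	1	father	NA	unaffected
F17	F17_UM	0	0	2	1	mother	NA	unaffected
F17	F17_P	F17_UF	F17_UM	2	2	proband	12	affected
F17	F17_AS1	F17_UF	F17_UM	1	2	sibling	8	affected
F17	F17_US1	F17_UF	F17_UM	1	1	sibling	NA	unaffected
F17	F17_US2	F17_UF	F17_UM	1	1	sibling	NA	unaffected
F19	F19_AF	0	0	1	2	father	NA	affected
F19	F19_UM	0	0	2	1	mother	NA	unaffected
F19	F19_P	F19_AF	F19_UM	1	2	proband	10	affected
F19	F19_US1	F19_AF	F19_UM	2	1	sibling	NA	unaffected
F19	F19_US2	F19_AF	F19_UM	2	1	sibling	NA	unaffected
F21	F21_UF	0	0	1	1	father	NA	unaffected
F21	F21_UM	0	0	2	1	mother	NA	unaffected
F21	F21_P	F21_UF	F21_UM	1	2	proband	10	affected
F21	F21_AS1	F21_UF	F21_UM	2	2	sibling	NA	affected
F22	F22_UF	0	0	1	1	father	NA	unaffected
F22	F22_UM	0	0	2	1	mother	NA	unaffected
F22	F22_P	F22_UF	F22_UM	1	2	proband	15	affected
F22	F22_AS1	F22_UF	F22_UM	1	2	sibling	14	affected
F22	F22_AS2	F22_UF	F22_UM	1	2	sibling	10	affected
F22	F22_AS3	F22_UF	F22_UM	1	2	sibling	5	affected
F24	F24_UF	0	0	1	1	father	NA	unaffected
F24	F24_UM	0	0	2	1	mother	NA	unaffected
F24	F24_P	F24_UF	F24_UM	1	2	proband	9	affected
F25	F25_UF	0	0	1	1	father	NA	unaffected
F25	F25_UM	0	0	2	1	mother	NA	unaffected
F25	F25_P	F25_UF	F25_UM	1	2	proband	16	affected
F25	F25_AS1	F25_UF	F25_UM	1	2	sibling	14	affected
F25	F25_AS2	F25_UF	F25_UM	1	2	sibling	13	affected
F25	F25_AS3	F25_UF	F25_UM	2	0	sibling	4	suspected
F25	F25_US1	F25_UF	F25_UM	1	1	sibling	NA	unaffected
F25	F25_US2	F25_UF	F25_UM	1	1	sibling	NA	unaffected
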
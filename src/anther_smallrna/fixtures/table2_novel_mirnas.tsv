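name	count	sequence	fold_energy
Mar-F-1-m0001	42	CGCUAUCCAUCCUGAGUUUCA	-50.60
Mar-F-1-m0002	8	UCUUGUACUGCAUCAUAACUU	-55.90
Mar-F-1-m0004	58	AGAGAUUGCAUUUCCUCUUCCA	-29.40
Mar-F-1-m0006	12	UAACUGAAGAGUUUGAUCAUGG	-90.50
Mar-F-1-m0011	24	UGCAAAUCCAGUCAAAAGUUA	-33.90
Mar-F-1-m0013	21	GGGAAUUUCUGAUUGUCGGGG	-46.30
Mar-F-1-m0017	34	UGCUCACUUCUCUUCUGUCAGC	-57.60
Mar-F-1-m0018	78	UUCCAUCUCUUGCACACUGGA	-44.60
Mar-F-1-m0019	13	CCAAGAGGAUUGAAGGCCAUG	-39.30
Mar-F-1-m0022	11	GAAGCGCCUGGCAAGUUAGAC	-42.80
Mar-F-1-m0024	72	CGAGCCGAAUCAAUAUCACUC	-40.10
Mar-F-1-m0025	30	AGCUGCUUGGCUAUGGAUCCC	-46.10
Mar-F-1-m0026	9	AUGACCAUUCAAGAAAGUGCU	-59.25
Mar-F-1-m0027	82	GUAGUUGAACGACGUUUAUCUA	-35.40
Mar-F-1-m0029	121	GGAGCAUCAUCAAGAUUCACA	-48.11
Mar-F-1-m0030	1765	UUACUUUAGAUGUCUCCUUCA	-48.92
Mar-F-1-m0031	52	UCCAAAGGGAUCGCAUUGAUC	-58.70
Mar-F-1-m0032	14	ACGUUAUGGGCAUGGUAUGGA	-50.92
Mar-F-1-m0033	12	CAUGACUUUUAGCGGCGUUUG	-32.80
Mar-F-1-m0035	6	UGGUUUUCAAGUGGGAUUUGCUG	-60.90
Mar-F-1-m0038	136	UUCAGAAACCAUCCCUUCCUU	-58.60
Mar-F-1-m0039	3138	ACAGCUUUAGAAAUCAUCCCU	-52.50
Mar-F-1-m0040	12	GCUCUCUAUGCUUCUGUCAUC	-55.00
Mar-F-1-m0041	9	AUAUGUUAGAUCAAAGAGUAA	-49.50
Mar-F-1-m0042	162	GGCUGUGGUUGAUUCGGCAAGA	-37.55
Mar-F-1-m0043	73	AAUGGAGGAGUUGGAAAGAUU	-37.39
Mar-F-1-m0044	14	AGUGGAUUGGGCUACAGUUUCUU	-27.10
Mar-F-1-m0048	6	AUAAAAUACUGAUGUGACAUA	-33.90
Mar-F-1-m0051	9	ACGGUUUUAAGUUUUAACUGA	-28.42
Mar-F-1-m0052	9	GACGGUUUUAAGUUUUAACUG	-28.42
Mar-F-1-m0053	12	UUGGCGAACAAAUCAGUAGGAGU	-20.80
Mar-F-1-m0054	8	ACGACAGAAAAAAGGAUUGAUCA	-30.30
Mar-F-1-m0055	21	AAGUGGGAUGGGUGGAAAGAUU	-40.90
Mar-F-2-m0006	12	GGAGGAUCUCCAGGACUUGGCUU	-36.69
Mar-F-2-m0014	219	GAUUUGGGGCAAAGACGGGAU	-42.80
Mar-F-2-m0016	7	CUGGAUGCAGAGGUUUAUCGA	-51.70
Mar-F-2-m0019	11	GUGAUUGGGCUAGGGUCUAGGCA	-28.84
Mar-F-2-m0020	9	AAAACUGGACUGUUGUAUUGGUU	-39.70
Mar-F-2-m0022	8	UUAGAUUCAUUGGCUGAGUUA	-95.50
Mar-F-2-m0034	65	AACCAAUGACUAUUCAUGAUUCC	-25.30
Mar-F-2-m0035	7	GGGAGAAAUUAGAUUGCCGA	-18.33
Mar-F-2-m0039	10	AAGCUUGCUAGGCUCAAAGCCCA	-20.00
Mar-F-2-m0043	11	GUUCGAUUCUCGGAAUGCCC	-56.80
Mar-F-2-m0046	14	GGAAGGGAUAUAACUCAGCGGUA	-28.60
Mar-F-2-m0051	12	AAAGGGAUGAUUUCUAAAGCU	-47.85
Mar-F-2-m0055	10	UAUGUUAGAUCAAAGAGUAAAUU	-48.90
Mar-F-2-m0058	18	UGCCUGGCUCCCUGUAUGCCU	-42.10
Mar-F-2-m0064	8	AUACGACUAGCGCGACUCGA	-83.97
Mar-F-2-m0065	10	AAGAGUCAGAUUGCAUUUUGC	-25.40
Mar-F-2-m0067	11	AGGUACAGAGUCUGUUGGCAU	-47.80
Mar-F-2-m0069	294	GAUGGGUGAGGGGGUAAGACA	-52.80
Mar-F-2-m0071	8	AAGAGAGAAAGAGAGGCCUGGA	-30.62
Mar-F-3-m0001	16	ACUAAAAAAUGGGCAAAUUAG	-70.85
Mar-F-3-m0002	12	CUUUGGAGGGGAGAUUAGAGC	-61.05
Mar-F-3-m0006	8	AGGGAAGGUUAGAUAUUUAUA	-77.80
Mar-F-3-m0008	46	UAGAGAUUGCAUUUCCUCUUCC	-29.40
Mar-F-3-m0014	10	CGUGGUGAUCAGUUGGACCUUU	-23.40
Mar-F-3-m0018	6	GGCAGCGGUUCAUCGAUCUCU	-28.70
Mar-F-3-m0029	5	UUUAAUUUCCUCCAAUAUCUUA	-46.64
Mar-F-3-m0031	23	UGCCUGGCUCCCUGAAUGCCA	-53.30
Mar-F-3-m0032	103	UAGCCAAGGAUGACUUGCCUG	-54.30
Mar-F-3-m0035	18	UGAUAUUGGCCUGGUUCACUC	-44.99
Mar-F-3-m0036	10	CUCUAUGGUAGAAUCAGUCGGGG	-42.60
Mar-F-3-m0038	458	UUCCACAGCUUUCUUGAACUU	-62.70
Mar-F-3-m0041	909	GGAAUGUUGUCUGGCUCGAGG	-50.90
Mar-F-3-m0043	35	AGAUCAUGUGGCAGUUUCACC	-45.64
Mar-F-3-m0044	7	AGAGCUUUCUUCAGUCCACUC	-82.60
Mar-F-3-m0048	111	UUGGUGCGGUUCAAUCAGAUA	-50.80
Mar-F-3-m0049	20	CGAAUGAUCUCGGACCAGGCU	-35.76
Mar-F-3-m0050	154	AUCAUGUGGCAGUUUCACCUG	-44.00
Mar-F-3-m0056	4369	UCUUGACCUUGUAAGACCUUU	-48.30
Mar-F-3-m0058	10	GGAAUGUUGGCUGGCUCGAAG	-52.60
Mar-F-3-m0064	38	UGAAUGAUUUCGGACCAGGCU	-40.80
Mar-F-3-m0065	28	UGGUGCAGGUCGGGAACUGAU	-76.37
Mar-F-3-m0067	65	UUCCACGGCUUUCUUGAACUU	-51.20
Mar-F-3-m0070	22	UGCAUUCUGAUGUAUGGGGAC	-69.07
Mar-F-3-m0080	14	UUUAAUAUUGUUUGGAUAUUGU	-32.70
Mar-F-3-m0087	5	CGGCAAGUUGUCUUUGGCUAC	-52.00
Mar-F-3-m0091	12	CAGGUGUAGCAUCAUCAAGAU	-63.81
Mar-F-3-m0092	30	UCAGGUCAUCUUGCAGCUUCA	-111.30
Mar-F-3-m0093	53	CGCUAUCUAUCCUGAGUUUCA	-61.50
Mar-F-3-m0095	26	UUGAAGACCCAUUUGCAACCAA	-24.80
Mar-F-3-m0110	15	CUCUUGUUGGGCAAAUGAGCAU	-22.10
Mar-F-3-m0113	6	UGGGAACUUGAAGAUGAGGCU	-29.40
Mar-F-3-m0115	15	AGGAGGAGCAGGAAGCAGUAACU	-56.90
Mar-F-3-m0120	6	UUUCAACAUAGUAGAGGGACU	-102.07
Mar-F-3-m0124	11	UAUAUGGCUUAAAACAGGCUCC	-78.30
Mar-F-3-m0127	21	UCUUUCCUACUCCUCCCAUUCC	-55.10
Mar-F-3-m0141	10	AUGGACAUCCAAGGGGGAGUGUU	-50.46
Mar-F-3-m0146	15	UCCCUUUGGAUGUCUUCUUGC	-75.70
Mar-F-3-m0164	22	UGGCUUCUAGACAGUGGAUGCA	-23.40
Mar-F-3-m0178	24	UGUUGGCUCGGUUCACUCAGA	-61.50
Mar-F-3-m0183	21	AUGCACUGCCUCUUCCCUGGC	-50.60
Mar-F-3-m0185	160	UGGAGGCAGCGGUUCAUCGAUC	-36.30
Mar-F-3-m0198	7	AAGAGUCAGAUUGCAUUUUG	-25.40
Mar-F-3-m0200	9	AGAGGUGAUCAUGGGCCGGG	-21.20
Mar-F-3-m0205	32	CAGCCCUGGUGUUGGACAUUC	-46.00
Mar-S-1-m0013	9	GGGGCUGCAUUGAAGUGAAGGCU	-76.70
Mar-S-1-m0014	7	UUCCACAGCUUUCUUGAACUG	-49.30
Mar-S-1-m0035	12	ACAGGACAGGACAGGACAGGACA	-68.99
Mar-S-1-m0039	13	UGGCGUAUGAGGAGCCAUGCA	-51.90
Mar-S-1-m0097	18	AUAUGGCUUAAAACAGGCUCCA	-78.30
Mar-S-1-m0110	8	AGAGGAGAAGAAAAUUCACUAUA	-45.65
Mar-S-2-m0027	7	AUUGGUGAUUGACAUUUUUAUCU	-33.10
Mar-S-2-m0040	67	GGAAUGGAGGAGUUGGAAAGA	-47.59
Mar-S-2-m0043	6	UCUUUGAUCUAAUAUACAGG	-40.30
Mar-S-2-m0046	7	AGUGUAAGACCUGUCUGGGACA	-28.50
Mar-S-2-m0051	6	CUGAGGUUGGGUCGGACGACA	-30.02
Mar-S-3-m0014	6	UCCAUGGUGGAGAUUGCUCUU	-30.00
Mar-S-3-m0041	16	UGUUGAAGGUCGAUGGGUUAA	-39.70
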
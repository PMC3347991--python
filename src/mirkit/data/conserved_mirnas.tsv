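name	mature	arm	au_pct	mfe	mfei
pde-miR159a	UUUGGUUUGAAGGGAGCUCUA	3p	53.5	-94.74	0.89
pde-miR162a	UCGAUAAACCUCUGCAUCCAG	3p	45.0	-49.10	0.80
pde-miR166a	UCGGACCAGGCUUCAUUCC	3p	45.8	-49.10	0.96
pde-miR166b	UCGGACCAGGCUUCAUUCC	3p	48.8	-43.40	1.01
pde-miR169a	CAGCCAAGGAUGACUUGCCUA	5p	58.3	-48.80	1.14
pde-miR171a	UGAUUGAGCCGUGCCAAUAUC	3p	55.2	-55.20	1.28
pde-miR390a	AAGCCCAGGAUGGAUAGCGCC	5p	53.7	-40.50	0.92
pde-miR396a	UCCCACGGCUUUCUUGAACUU	5p	55.1	-43.28	0.90
pde-miR482a	UCUUUCCUACUCCUCCCAUUCC	3p	52.3	-60.90	0.98
pde-miR482b	UCUUCCCUAUUCCUCCCAUUCC	3p	52.1	-60.30	1.04
pde-miR482c	GGCUUGCGAGGGUAGGAAAAG	5p	48.9	-45.20	0.90
pde-miR482d	CCUUUCCAACGCCUCCCAUGCC	3p	54.8	-46.50	0.76
pde-miR783	AUUCUUUGCUGGUUCAUUUUC	3p	57.0	-26.80	0.67
pde-miR946a	CAGCCCUUCUCCUAUCCACAA	3p	59.3	-71.50	1.02
pde-miR947	CAUCGGAAUCUGUUACUGUUUC	3p	48.7	-70.70	0.94
pde-miR949a	UCUCUAGGAAUCAAAUGUGUC	5p	47.7	-41.80	0.91
pde-miR949b	UCUCCGGGAAUCCAAUGCGCC	5p	46.3	-66.30	1.12
pde-miR950a	UCUGGUCCACGGUGGUUUAU	5p	57.2	-40.90	1.05
pde-miR951	UGUUCUUGACGUCUGGACCAC	5p	54.8	-43.00	0.83
pde-miR952a	AACAGAGCAUGCCAUUGGUG	5p	54.0	-232.79	0.96
pde-miR952b	AACAGAGCAUGCCAUUGGUG	5p	53.9	-214.40	0.99
pde-miR952c	AACAGAACAUGCCAUUGGUG	5p	54.2	-192.12	0.90
pde-miR1310	GGCAUCGGGGGCGUAACGCCCU	5p	47.0	-35.00	0.80
pde-miR1311	UCAGAGUUUUGCCAGUUCCGCC	3p	48.8	-43.40	0.99
pde-miR1312a	UUUGGAGAGAAAAUGGCGACAU	3p	62.8	-41.50	0.81
pde-miR1313	UACCACUGAAAUUGUUGUUCG	5p	58.6	-66.72	0.71
pde-miR1314a	CCGGCCUCGAAUGUUAGGAGAA	3p	56.2	-42.30	0.92
pde-miR1448	CUUUCCAACGCCUCCCAUGC	3p	54.8	-46.50	0.76
pde-miR2118a	UUUCCAACGCCUCCCAUGCCUA	3p	54.8	-46.50	0.76
pde-miR2118b	UUCCCUAUUCCUCCCAUUCCUA	3p	49.4	-42.00	0.98
pde-miR3701	UGAACAAUGCCCACCCUUCAUC	3p	59.3	-84.10	1.07
pde-miR3704a	GGUCUCGGUGGAGUUGGGAAGA	5p	53.8	-49.00	0.98
pde-miR3704b	GGUCUCGAUGGAGUUGGGAAGA	5p	54.7	-46.40	0.95
pde-miR3712	UGUGAUCAAGAUCAGACUCCCA	5p	59.4	-15.00	0.54
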
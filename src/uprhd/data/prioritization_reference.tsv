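gene	UPRE	ERSE-I	ERSE-II	interaction_type	rho	fdr_cor
RAB5A	+	+	-	indirect	0.48	0.0038
HMGB1	+	+	-	indirect	0.39	0.026
CTNNB1	-	+	-	direct	0.82	0
DNM1	+	+	-	direct	0.55	0.00050
TCP1	+	+	-	indirect	0.62	0.00014
TUBB	+	+	-	indirect	0.60	0.00025
TSG101	+	+	-	indirect	0.73	0
DNAJB1	+	-	+	indirect	-0.22	1
CCT2	-	-	-	indirect	0.79	0
EEF2	-	-	-	indirect	0.81	0
DYNC1H1	-	-	-	indirect	0.57	0.00038
HSPA5	-	-	-	indirect	0.07	0.81
SLC12A5	-	-	-	indirect	-0.06	1
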
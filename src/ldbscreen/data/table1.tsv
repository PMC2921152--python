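dgrc	symbol	Dlmo	ssdp	Chip
CG10229	katanin-60	+	+	0
CG10236	LanA	+	0	-
CG11334	CG11334	-	n	n
CG11893	CG11893	+	+	+
CG12163	CG12163	+	+	0
CG12389	Fpps	+	0	0
CG12755	l(3)mbn	+	0	-
CG12800	Cyp6d4	+	+	0
CG14204	CG14204	+	-	0
CG1469	Fer2LCH	0	+	0
CG1518	CG1518	+	0	+
CG15489	CG15489	+	0	0
CG2604	CG2604	+	-	0
CG2674	M(2)21AB	-	+	-
CG2767	CG2767	+	+	0
CG2803	CG2803	0	n	n
CG2835	G-salpha60A	+	0	-
CG2986	oho23B	0	n	n
CG31689	CG31689	0	n	n
CG3186	eIF-5A	+	0	0
CG31991	mdy	+	0	0
CG3340	Kr	+	n	n
CG3488	CG3488	+	0	-
CG3725	Ca-P60A	0	n	n
CG4080	CG4080	+	0	+
CG4087	RpP2	+	0	-
CG4663	CG4663	0	n	n
CG4719	BcDNA:LD22548	+	-	-
CG4775	l(2)k00619	+	n	n
CG5431	CG5431	0	n	n
CG5446	CG5446	+	0	0
CG5725	fbl	0	0	0
CG6687	CG6687	0	+	0
CG6803	CG6803	+	+	+
CG7115	BcDNA:LD21794	0	n	n
CG7755	CG7755	0	-	-
CG7758	ppl	+	n	n
CG9415	xbp1	+	-	-
CG9932	CG9932	-	0	-
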
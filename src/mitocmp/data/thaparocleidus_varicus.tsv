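# id: MN151339
# organism: Thaparocleidus varicus
# length: 14088
# circular: true
gene	start	end	size	intergenic	start_codon	stop_codon	anticodon	identity_pct
cox1	1	1557	1557		ATT	TAG		82.59
trnC	1566	1630	65	8			GCA	87.69
cox2	1634	2260	627	3	GTG	TAA		77.35
nad6	2261	2707	447	0	ATG	TAG		72.48
trnL1	2708	2776	69				TAG	78.26
trnS2	2777	2843	67				TGA	77.61
trnL2	2850	2914	65	6			TAA	87.69
trnR	2916	2981	66	1			TCG	72.46
nad5	2983	4548	1566	1	ATG	TAA		68.89
trnK	5027	5091	65	478			CTT	86.36
trnT	5094	5159	66	2			TGT	86.36
trnW	5162	5225	64	2			TCA	93.75
trnY	5232	5295	64	6			GTA	93.85
trnS1	5301	5357	57	5			GCT	82.46
rrnL	5358	6297	940					84.93
rrnS	6298	7030	733					85.56
trnE	7031	7093	63				TTC	77.78
trnG	7131	7196	66	37			TCC	80.6
cox3	7613	8284	672	416	ATG	TAA		76.64
trnH	8265	8328	64	-20			GTG	89.06
cytb	8329	9405	1077		ATG	TAA		84.22
nad4L	9405	9656	252	-1	ATG	TAG		76.59
nad4	9629	10846	1218	-28	TTG	TAA		71.73
trnQ	10849	10911	63	2			TTG	85.71
trnF	10910	10974	65	-2			GAA	98.46
trnM	10967	11030	64	-8			CAT	92.31
atp6	11031	11543	513	0	ATG	TAA		76.02
nad2	11544	12371	828	0	ATG	TAA		69.2
trnV	12372	12435	64	0			TAC	81.54
trnA	12436	12503	68				TGC	82.35
trnD	12504	12566	63	0			GTC	81.25
nad1	12567	13466	900		GTG	TAA		80.56
trnN	13468	13530	63	1			GTT	84.38
trnP	13573	13639	67	42			TGG	83.82
trnI	13639	13704	66	-1			GAT	92.54
nad3	13711	14073	363	6	ATG	TAA		75.21
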
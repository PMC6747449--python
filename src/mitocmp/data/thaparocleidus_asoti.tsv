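# id: MN151340
# organism: Thaparocleidus asoti
# length: 16074
# circular: true
gene	start	end	size	intergenic	start_codon	stop_codon	anticodon	identity_pct
cox1	1	1554	1554		ATG	TAG		82.59
trnC	1554	1617	64	-1			GCA	87.69
cox2	1621	2245	625	3	ATG	T--		77.35
nad6	2247	2693	447	1	GTG	TAA		72.48
trnL1	2694	2758	65				TAG	78.26
trnS2	2759	2825	67				TGA	77.61
trnL2	2831	2895	65	5			TAA	87.69
trnR	2896	2963	68	0			TCG	72.46
nad5	2966	4537	1572	2	ATG	TAA		68.89
trnK	6558	6622	65	2020			CTT	86.36
trnT	6623	6686	64	0			TGT	86.36
trnW	6689	6751	63	2			TCA	93.75
trnY	6752	6814	63	0			GTA	93.85
trnS1	6838	6894	57	23			GCT	82.46
rrnL	6895	7828	934					84.93
rrnS	7829	8550	722					85.56
trnE	8551	8611	61				TTC	77.78
trnG	8620	8686	67	8			TCC	80.6
cox3	9479	10150	672	792	ATG	TAA		76.64
trnH	10131	10192	62	-20			GTG	89.06
cytb	10193	11269	1077		ATG	TAA		84.22
nad4L	11269	11520	252	-1	ATG	TAG		76.59
nad4	11608	12852	1245	87	ATG	TAG		71.73
trnQ	12856	12916	61	3			TTG	85.71
trnF	12915	12979	65	-2			GAA	98.46
trnM	12971	13035	65	-9			CAT	92.31
atp6	13039	13548	510	3	ATG	TAG		76.02
nad2	13552	14373	822	3	ATG	TAA		69.2
trnV	14378	14442	65	4			TAC	81.54
trnA	14443	14506	64				TGC	82.35
trnD	14506	14568	63	-1			GTC	81.25
nad1	14569	15468	900		ATG	TAA		80.56
trnN	15475	15538	64	6			GTT	84.38
trnP	15562	15626	65	23			TGG	83.82
trnI	15626	15692	67	-1			GAT	92.54
nad3	15696	16058	363	3	ATG	TAA		75.21
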
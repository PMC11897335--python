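gene	class	strand	start	end	anticodon
trnM	tRNA	+	1	66	CAU
trnI	tRNA	+	67	130	GAU
trnQ	tRNA	-	128	196	UUG
nad2	PCG	+	259	1272	.
trnW	tRNA	+	1271	1340	UCA
trnC	tRNA	-	1333	1401	GCA
trnY	tRNA	-	1439	1503	GUA
cox1	PCG	+	1507	3042	.
trnL1	tRNA	+	3038	3107	UAA
cox2	PCG	+	3108	3789	.
trnK	tRNA	+	3793	3864	UUU
trnD	tRNA	+	3895	3961	GUC
atp8	PCG	+	3962	4126	.
atp6	PCG	+	4120	4797	.
cox3	PCG	+	4797	5585	.
trnG	tRNA	+	5588	5654	UCC
nad3	PCG	+	5655	6008	.
trnA	tRNA	+	6014	6081	UGC
trnR	tRNA	+	6081	6144	UCG
trnN	tRNA	+	6145	6209	GUU
trnS1	tRNA	+	6211	6276	UCU
trnE	tRNA	+	6284	6352	UUC
trnF	tRNA	-	6388	6454	GAA
nad5	PCG	-	6456	8192	.
trnH	tRNA	-	8193	8259	GUG
nad4	PCG	-	8260	9598	.
nad4l	PCG	-	9600	9887	.
trnT	tRNA	+	9897	9961	UGU
trnP	tRNA	-	9962	10027	UGG
nad6	PCG	+	10030	10560	.
cytb	PCG	+	10572	11720	.
trnS2	tRNA	+	11735	11801	UGA
nad1	PCG	-	11819	12760	.
trnL2	tRNA	-	12762	12830	UAG
rrnL	rRNA	-	12831	14164	.
trnV	tRNA	-	14166	14234	UAC
rrnS	rRNA	-	14235	15010	.
CR	CR	+	15011	15385	.
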
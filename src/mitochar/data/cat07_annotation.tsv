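gene	class	strand	start	end	anticodon
trnM	tRNA	+	1	66	CAU
trnI	tRNA	+	67	130	GAU
trnQ	tRNA	-	128	196	UUG
nad2	PCG	+	259	1272	.
trnW	tRNA	+	1271	1340	UCA
trnC	tRNA	-	1333	1401	GCA
trnY	tRNA	-	1437	1501	GUA
cox1	PCG	+	1505	3040	.
trnL1	tRNA	+	3036	3105	UAA
cox2	PCG	+	3106	3787	.
trnK	tRNA	+	3791	3862	UUU
trnD	tRNA	+	3893	3959	GUC
atp8	PCG	+	3960	4124	.
atp6	PCG	+	4118	4795	.
cox3	PCG	+	4795	5583	.
trnG	tRNA	+	5586	5652	UCC
nad3	PCG	+	5653	6006	.
trnA	tRNA	+	6012	6079	UGC
trnR	tRNA	+	6079	6142	UCG
trnN	tRNA	+	6143	6207	GUU
trnS1	tRNA	+	6209	6274	UCU
trnE	tRNA	+	6282	6350	UUC
trnF	tRNA	-	6396	6462	GAA
nad5	PCG	-	6464	8200	.
trnH	tRNA	-	8201	8267	GUG
nad4	PCG	-	8268	9606	.
nad4l	PCG	-	9608	9895	.
trnT	tRNA	+	9905	9969	UGU
trnP	tRNA	-	9970	10035	UGG
nad6	PCG	+	10038	10568	.
cytb	PCG	+	10580	11728	.
trnS2	tRNA	+	11743	11809	UGA
nad1	PCG	-	11827	12768	.
trnL2	tRNA	-	12770	12838	UAG
rrnL	rRNA	-	12839	14174	.
trnV	tRNA	-	14176	14244	UAC
rrnS	rRNA	-	14245	15020	.
CR	CR	+	15021	15395	.
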
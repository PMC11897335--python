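gene	length_cat07	length_cat08	gap_cat07	gap_cat08	start_codon	stop_codon
trnM	66	66	0	0	.	.
trnI	64	64	-3	-3	.	.
trnQ	69	69	62	62	.	.
nad2	1014	1014	-2	-2	ATT	TAA
trnW	70	70	-8	-8	.	.
trnC	69	69	35	37	.	.
trnY	65	65	3	3	.	.
cox1	1536	1536	-5	-5	CGA	TAA
trnL1	70	70	0	0	.	.
cox2	682	682	3	3	ATG	T
trnK	72	72	30	30	.	.
trnD	67	67	0	0	.	.
atp8	165	165	-7	-7	ATT	TAA
atp6	678	678	-1	-1	ATG	TAA
cox3	789	789	2	2	ATG	TAA
trnG	67	67	0	0	.	.
nad3	354	354	5	5	ATT	TAA
trnA	68	68	-1	-1	.	.
trnR	64	64	0	0	.	.
trnN	65	65	1	1	.	.
trnS1	66	66	7	7	.	.
trnE	69	69	45	35	.	.
trnF	67	67	1	1	.	.
nad5	1737	1737	0	0	ATT	TAA
trnH	67	67	0	0	.	.
nad4	1339	1339	1	1	ATG	T
nad4l	288	288	9	9	ATG	TAA
trnT	65	65	0	0	.	.
trnP	66	66	2	2	.	.
nad6	531	531	11	11	ATT	TAA
cytb	1149	1149	14	14	ATG	TAA
trnS2	67	67	17	17	.	.
nad1	942	942	1	1	ATG	TAA
trnL2	69	69	0	0	.	.
rrnL	1336	1334	1	1	.	.
trnV	69	69	0	0	.	.
rrnS	776	776	0	0	.	.
CR	375	375	.	.	.	.
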
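##gff-version 3
ctg1	toy	gene	801	1000	.	+	.	ID=gB
ctg1	toy	gene	5001	6000	.	+	.	ID=gA
ctg2	toy	gene	101	400	.	-	.	ID=gC
ctg2	toy	gene	451	600	.	+	.	ID=gD
ctg3	toy	gene	1	900	.	+	.	ID=gE
ctg3	toy	gene	1001	2000	.	-	.	ID=gF
ctg3	toy	gene	2501	3000	.	+	.	ID=gG
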
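chr1	0	30375000	p4	gneg
chr1	30375000	60750000	p3	gpos50
chr1	60750000	91125000	p2	gneg
chr1	91125000	121500000	p1	gpos75
chr1	121500000	125000000	p11.1	acen
chr1	125000000	128900000	q11.1	acen
chr1	128900000	152970124	q12	gpos50
chr1	152970124	177040248	q13	gneg
chr1	177040248	201110372	q14	gpos75
chr1	201110372	225180496	q15	gneg
chr1	225180496	249250621	q16	gpos50
chr2	0	22625000	p4	gneg
chr2	22625000	45250000	p3	gpos50
chr2	45250000	67875000	p2	gneg
chr2	67875000	90500000	p1	gpos75
chr2	90500000	93300000	p11.1	acen
chr2	93300000	96800000	q11.1	acen
chr2	96800000	126079874	q12	gpos50
chr2	126079874	155359748	q13	gneg
chr2	155359748	184639622	q14	gpos75
chr2	184639622	213919496	q15	gneg
chr2	213919496	243199373	q16	gpos50
chr3	0	21975000	p4	gneg
chr3	21975000	43950000	p3	gpos50
chr3	43950000	65925000	p2	gneg
chr3	65925000	87900000	p1	gpos75
chr3	87900000	91000000	p11.1	acen
chr3	91000000	93900000	q11.1	acen
chr3	93900000	114724486	q12	gpos50
chr3	114724486	135548972	q13	gneg
chr3	135548972	156373458	q14	gpos75
chr3	156373458	177197944	q15	gneg
chr3	177197944	198022430	q16	gpos50
chr4	0	12050000	p4	gneg
chr4	12050000	24100000	p3	gpos50
chr4	24100000	36150000	p2	gneg
chr4	36150000	48200000	p1	gpos75
chr4	48200000	50400000	p11.1	acen
chr4	50400000	52700000	q11.1	acen
chr4	52700000	80390855	q12	gpos50
chr4	80390855	108081710	q13	gneg
chr4	108081710	135772565	q14	gpos75
chr4	135772565	163463420	q15	gneg
chr4	163463420	191154276	q16	gpos50
chr5	0	11525000	p4	gneg
chr5	11525000	23050000	p3	gpos50
chr5	23050000	34575000	p2	gneg
chr5	34575000	46100000	p1	gpos75
chr5	46100000	48400000	p11.1	acen
chr5	48400000	50700000	q11.1	acen
chr5	50700000	76743052	q12	gpos50
chr5	76743052	102786104	q13	gneg
chr5	102786104	128829156	q14	gpos75
chr5	128829156	154872208	q15	gneg
chr5	154872208	180915260	q16	gpos50
chr6	0	14675000	p4	gneg
chr6	14675000	29350000	p3	gpos50
chr6	29350000	44025000	p2	gneg
chr6	44025000	58700000	p1	gpos75
chr6	58700000	61000000	p11.1	acen
chr6	61000000	63300000	q11.1	acen
chr6	63300000	84863013	q12	gpos50
chr6	84863013	106426026	q13	gneg
chr6	106426026	127989039	q14	gpos75
chr6	127989039	149552052	q15	gneg
chr6	149552052	171115067	q16	gpos50
chr7	0	14500000	p4	gneg
chr7	14500000	29000000	p3	gpos50
chr7	29000000	43500000	p2	gneg
chr7	43500000	58000000	p1	gpos75
chr7	58000000	59900000	p11.1	acen
chr7	59900000	61700000	q11.1	acen
chr7	61700000	81187732	q12	gpos50
chr7	81187732	100675464	q13	gneg
chr7	100675464	120163196	q14	gpos75
chr7	120163196	139650928	q15	gneg
chr7	139650928	159138663	q16	gpos50
chr8	0	10775000	p4	gneg
chr8	10775000	21550000	p3	gpos50
chr8	21550000	32325000	p2	gneg
chr8	32325000	43100000	p1	gpos75
chr8	43100000	45600000	p11.1	acen
chr8	45600000	48100000	q11.1	acen
chr8	48100000	67752804	q12	gpos50
chr8	67752804	87405608	q13	gneg
chr8	87405608	107058412	q14	gpos75
chr8	107058412	126711216	q15	gneg
chr8	126711216	146364022	q16	gpos50
chr9	0	11825000	p4	gneg
chr9	11825000	23650000	p3	gpos50
chr9	23650000	35475000	p2	gneg
chr9	35475000	47300000	p1	gpos75
chr9	47300000	49000000	p11.1	acen
chr9	49000000	50700000	q11.1	acen
chr9	50700000	68802686	q12	gpos50
chr9	68802686	86905372	q13	gneg
chr9	86905372	105008058	q14	gpos75
chr9	105008058	123110744	q15	gneg
chr9	123110744	141213431	q16	gpos50
chr10	0	19000000	p2	gneg
chr10	19000000	38000000	p1	gpos50
chr10	38000000	40200000	p11.1	acen
chr10	40200000	42300000	q11.1	acen
chr10	42300000	60946949	q12	gpos50
chr10	60946949	79593898	q13	gneg
chr10	79593898	98240847	q14	gpos75
chr10	98240847	116887796	q15	gneg
chr10	116887796	135534747	q16	gpos50
chr11	0	12900000	p4	gneg
chr11	12900000	25800000	p3	gpos50
chr11	25800000	38700000	p2	gneg
chr11	38700000	51600000	p1	gpos75
chr11	51600000	53700000	p11.1	acen
chr11	53700000	55700000	q11.1	acen
chr11	55700000	71561303	q12	gpos50
chr11	71561303	87422606	q13	gneg
chr11	87422606	103283909	q14	gpos75
chr11	103283909	119145212	q15	gneg
chr11	119145212	135006516	q16	gpos50
chr12	0	16650000	p2	gneg
chr12	16650000	33300000	p1	gpos50
chr12	33300000	35800000	p11.1	acen
chr12	35800000	38200000	q11.1	acen
chr12	38200000	57330379	q12	gpos50
chr12	57330379	76460758	q13	gneg
chr12	76460758	95591137	q14	gpos75
chr12	95591137	114721516	q15	gneg
chr12	114721516	133851895	q16	gpos50
chr13	0	8150000	p2	gneg
chr13	8150000	16300000	p1	gpos50
chr13	16300000	17900000	p11.1	acen
chr13	17900000	19500000	q11.1	acen
chr13	19500000	38633975	q12	gpos50
chr13	38633975	57767950	q13	gneg
chr13	57767950	76901925	q14	gpos75
chr13	76901925	96035900	q15	gneg
chr13	96035900	115169878	q16	gpos50
chr14	0	8050000	p2	gneg
chr14	8050000	16100000	p1	gpos50
chr14	16100000	17600000	p11.1	acen
chr14	17600000	19100000	q11.1	acen
chr14	19100000	36749908	q12	gpos50
chr14	36749908	54399816	q13	gneg
chr14	54399816	72049724	q14	gpos75
chr14	72049724	89699632	q15	gneg
chr14	89699632	107349540	q16	gpos50
chr15	0	7900000	p2	gneg
chr15	7900000	15800000	p1	gpos50
chr15	15800000	19000000	p11.1	acen
chr15	19000000	20700000	q11.1	acen
chr15	20700000	37066278	q12	gpos50
chr15	37066278	53432556	q13	gneg
chr15	53432556	69798834	q14	gpos75
chr15	69798834	86165112	q15	gneg
chr15	86165112	102531392	q16	gpos50
chr16	0	17300000	p2	gneg
chr16	17300000	34600000	p1	gpos50
chr16	34600000	36600000	p11.1	acen
chr16	36600000	38600000	q11.1	acen
chr16	38600000	55851584	q12	gpos50
chr16	55851584	73103168	q13	gneg
chr16	73103168	90354753	q14	gpos75
chr17	0	11100000	p2	gneg
chr17	11100000	22200000	p1	gpos50
chr17	22200000	24000000	p11.1	acen
chr17	24000000	25800000	q11.1	acen
chr17	25800000	44265070	q12	gpos50
chr17	44265070	62730140	q13	gneg
chr17	62730140	81195210	q14	gpos75
chr18	0	7700000	p2	gneg
chr18	7700000	15400000	p1	gpos50
chr18	15400000	17200000	p11.1	acen
chr18	17200000	19000000	q11.1	acen
chr18	19000000	38692416	q12	gpos50
chr18	38692416	58384832	q13	gneg
chr18	58384832	78077248	q14	gpos75
chr19	0	12200000	p2	gneg
chr19	12200000	24400000	p1	gpos50
chr19	24400000	26500000	p11.1	acen
chr19	26500000	28600000	q11.1	acen
chr19	28600000	38776327	q12	gpos50
chr19	38776327	48952654	q13	gneg
chr19	48952654	59128983	q14	gpos75
chr20	0	12800000	p2	gneg
chr20	12800000	25600000	p1	gpos50
chr20	25600000	27500000	p11.1	acen
chr20	27500000	29400000	q11.1	acen
chr20	29400000	40608506	q12	gpos50
chr20	40608506	51817012	q13	gneg
chr20	51817012	63025520	q14	gpos75
chr21	0	5450000	p2	gneg
chr21	5450000	10900000	p1	gpos50
chr21	10900000	13200000	p11.1	acen
chr21	13200000	14300000	q11.1	acen
chr21	14300000	25576631	q12	gpos50
chr21	25576631	36853262	q13	gneg
chr21	36853262	48129895	q14	gpos75
chr22	0	6100000	p2	gneg
chr22	6100000	12200000	p1	gpos50
chr22	12200000	14700000	p11.1	acen
chr22	14700000	17900000	q11.1	acen
chr22	17900000	29034855	q12	gpos50
chr22	29034855	40169710	q13	gneg
chr22	40169710	51304566	q14	gpos75
chrX	0	14525000	p4	gneg
chrX	14525000	29050000	p3	gpos50
chrX	29050000	43575000	p2	gneg
chrX	43575000	58100000	p1	gpos75
chrX	58100000	60600000	p11.1	acen
chrX	60600000	63000000	q11.1	acen
chrX	63000000	81454112	q12	gpos50
chrX	81454112	99908224	q13	gneg
chrX	99908224	118362336	q14	gpos75
chrX	118362336	136816448	q15	gneg
chrX	136816448	155270560	q16	gpos50
chrY	0	5800000	p2	gneg
chrY	5800000	11600000	p1	gpos50
chrY	11600000	12500000	p11.1	acen
chrY	12500000	13400000	q11.1	acen
chrY	13400000	28724522	q12	gpos50
chrY	28724522	44049044	q13	gneg
chrY	44049044	59373566	q14	gpos75
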
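genome	gene	category	strand	segments	length	gc	init_codon	term_codon	intergenic
genome1	tRNA-Thr	tRNA	N	4421-4492	72	51.39
genome1	orf309	PCG	J	7042-7092;10274-10531	309		ATG	TAA	2549
genome1	matR	PCG	J	7756-9723	1968	51.78	ATG	TAG	663
genome1	ccmFc	other	N	12975-13523;14475-15242	1317		ATG	TGA	3251
genome1	ccmFn	other	J	37088-38716	1629	45.30	ATG	TAA	21845
genome1	nad7	PCG	N	47657-47917;49703-50413;51678-51746;52647-52790	1185		ATG	TAG	8940
genome1	atp6	PCG	J	66186-67004	819	37.61	ACG	TAA	13395
genome1	rpl16	PCG	N	72277-72792	516	44.57	ATG	TAA	5272
genome1	rps3	PCG	N	72683-74287;76033-76101	1674		ATG	TAG	-110
genome1	tRNA-Tyr	tRNA	N	91413-91496	84	50.00			15311
genome1	tRNA-Asn	tRNA	N	92321-92392	72	52.78			824
genome1	tRNA-Cys	tRNA	N	94407-94478	72	51.39			2014
genome1	atp9	PCG	N	99941-100186	246	45.53	ATG	TAA	5462
genome1	tRNA-Arg	tRNA	J	104397-104467	71	43.66			4210
genome2	nad2	PCG	N	1-153;186243-186401;188825-189397;190869-191057;303715-304107	1467	38.72	ATG	TAA
genome2	tRNA-Thr	tRNA	N	15576-15647	72	51.39			15422
genome2	cox2	PCG	J	17577-17996;19517-19879	783	40.74	ATG	TAA	1929
genome2	rrn26	rRNA	N	31879-35307	3429	50.22			11999
genome2	ccmC	other	N	41488-42240	753	43.69	ATG	TAA	6180
genome2	rrn5	rRNA	N	42414-42529	116	53.45			173
genome2	rrn18	rRNA	N	42691-44531	1841	53.56			161
genome2	mttB	other	J	57829-58668	840	41.79	ATG	TAG	13297
genome2	tRNA-Ser	tRNA	J	64038-64125	88	51.14			5369
genome2	atp4	PCG	N	67536-68123	588	42.01	ATG	TGA	3410
genome2	nad4L	PCG	N	68311-68613	303	35.97	ATG	TAA	187
genome2	tRNA-Lys	tRNA	N	75008-75082	75	46.67			6394
genome2	ccmB	other	J	77440-78060	621	41.38	ATG	TGA	2357
genome2	rpl10	PCG	N	78351-78839	489	41.51	ATG	TAA	290
genome2	rps1	PCG	J	81832-82437	606	42.08	ATG	TAA	2992
genome2	tRNA-Met	tRNA	J	89045-89121	77	44.16			6607
genome2	orf954	PCG	N	93928-94413;95766-95846;140865-141251	954	43.50	ATG	TAA	4806
genome2	rps13	PCG	N	96776-97126	351	39.32	ATG	TGA	929
genome2	tRNA-Gly	tRNA	J	104293-104366	74	54.05			7166
genome2	tRNA-Gln	tRNA	J	107333-107404	72	47.22			2966
genome2	tRNA-Ile	tRNA	N	108714-108789	76	35.53			1309
genome2	atp1	PCG	J	108877-110406	1530	43.86	ATG	TAA	87
genome2	rpl5	PCG	J	112970-113524	555	42.16	ATG	TAA	2563
genome2	orf108	PCG	J	113526-113633	108	35.19	ATG	TAG	1
genome2	cob	PCG	J	115168-116349	1182	40.52	ATG	TGA	1534
genome2	rps12	PCG	N	117371-117748	378	43.65	ATG	TGA	1021
genome2	nad3	PCG	N	117797-118153	357	40.62	ATG	TAA	48
genome2	tRNA-Val	tRNA	N	132275-132334	60	50.00			14121
genome2	rrn18	rRNA	J	133925-135765	1841	53.56			1590
genome2	rrn5	rRNA	J	135927-136041	115	53.04			161
genome2	ccmC	other	J	136215-136967	753	43.69	ATG	GAA	173
genome2	rrn26	rRNA	J	143147-146575	3429	50.22			6179
genome2	cox2	PCG	N	158575-158937;160458-160877	783	40.74	ATG	TAA	11999
genome2	tRNA-Thr	tRNA	J	162807-162878	72	51.39			1929
genome2	tRNA-Arg	tRNA	N	172669-172739	71	43.66			9790
genome2	atp9	PCG	J	176950-177195	246	45.53	ATG	TAA	4210
genome2	nad5	PCG	J	177495-177722;178573-179787;261418-261810;262913-263062	1986	40.89	ATG	TAA	299
genome2	tRNA-Cys	tRNA	J	182658-182729	72	51.39			2870
genome2	tRNA-Asn	tRNA	J	184744-184815	72	52.78			2014
genome2	tRNA-Tyr	tRNA	J	185640-185723	84	50.00			824
genome2	rps10	PCG	J	202042-202293;203144-203224	333	37.84	ACG	TGA	16318
genome2	cox1	PCG	J	203424-205007	1584	42.87	ATG	TAA	199
genome2	nad6	PCG	J	215496-216113	618	40.13	ATG	TAA	10488
genome2	tRNA-Val	tRNA	J	217699-217758	60	50.00			1585
genome2	nad3	PCG	J	231877-232233	357	40.62	ATG	TAA	14118
genome2	rps12	PCG	J	232282-232659	378	43.65	ATG	TGA	48
genome2	cob	PCG	N	233681-234862	1182	40.52	ATG	TGA	1021
genome2	orf108	PCG	N	236398-236505	108	35.19	ATG	TAG	1535
genome2	rpl5	PCG	N	236507-237061	555	42.16	ATG	TAA	1
genome2	atp1	PCG	N	239625-241154	1530	43.86	ATG	TAA	2563
genome2	tRNA-Ile	tRNA	J	241242-241317	76	35.53			87
genome2	tRNA-Gln	tRNA	N	242627-242698	72	47.22			1309
genome2	tRNA-Gly	tRNA	N	245665-245738	74	54.05			2966
genome2	atp8	PCG	J	252332-252811	480	41.04	ATG	TAA	6593
genome2	cox3	PCG	J	253922-254719	798	43.23	ATG	TGA	1110
genome2	sdh4	PCG	J	254647-255078	432	40.74	ATG	TGA	-73
genome2	rps4	PCG	N	256045-256875	831	39.47	ATG	TAA	966
genome2	tRNA-Leu	tRNA	J	256059-256123	65	46.15			-817
genome2	rpl2	PCG	J	258510-259376;260429-260479;260484-260543	978	49.49	ATG	TAA	2386
genome2	tRNA-Ala	tRNA	J	261648-261712	65	40.00			1104
genome2	tRNA-Trp	tRNA	N	269778-269851	74	52.70			8065
genome2	nad9	PCG	N	274043-274615	573	41.19	ATG	TAA	4191
genome2	tRNA-His	tRNA	N	278687-278761	75	60.00			4071
genome2	tRNA-Glu	tRNA	J	280888-280959	72	50.00			2126
genome2	tRNA-Ser	tRNA	J	283072-283159	88	44.32			2112
genome2	tRNA-Phe	tRNA	J	283411-283484	74	47.30			251
genome2	tRNA-Pro	tRNA	J	283740-283814	75	54.67			255
genome2	tRNA-Asp	tRNA	N	289908-289981	74	63.51			6093
genome2	nad4	PCG	J	292242-292703;294113-294628;297800-298219;300710-300799	1488	40.59	ATG	TGA	2260
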
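# synthetic stand-in fixture: generator output at seed 20221024
# 159 biallelic loci, founder-enriched ASJ-like vs NFE-like tallies
locus_id	A	C	G	T
1:1000000C>A	112	119888	0	0
1:1000001C>G	0	119966	34	0
1:1000002T>C	0	137	0	119863
1:1000003A>C	119832	168	0	0
1:1000004A>G	119963	0	37	0
1:1000005A>G	119989	0	11	0
1:1000006T>A	41	0	0	119959
1:1000007C>A	195	119805	0	0
1:1000008T>C	0	171	0	119829
1:1000009T>G	0	0	169	119831
1:1000010C>T	0	119758	0	242
1:1000011T>G	0	0	143	119857
1:1000012A>G	119867	0	133	0
1:1000013A>T	119955	0	0	45
1:1000014G>T	0	0	119798	202
1:1000015G>T	0	0	119995	5
1:1000016A>T	119961	0	0	39
1:1000017G>A	65	0	119935	0
1:1000018C>A	179	119821	0	0
1:1000019T>A	149	0	0	119851
1:1000020A>T	119940	0	0	60
1:1000021T>C	0	141	0	119859
1:1000022G>C	0	216	119784	0
1:1000023T>C	0	40	0	119960
1:1000024A>T	119970	0	0	30
1:1000025A>G	119909	0	91	0
1:1000026A>T	119864	0	0	136
1:1000027T>C	0	114	0	119886
1:1000028G>T	0	0	119848	152
1:1000029G>T	0	0	119818	182
1:1000030A>C	119847	153	0	0
1:1000031A>T	119892	0	0	108
1:1000032A>C	119926	74	0	0
1:1000033A>G	119851	0	149	0
1:1000034C>T	0	119928	0	72
1:1000035A>T	119914	0	0	86
1:1000036T>C	0	119	0	119881
1:1000037G>C	0	102	119898	0
1:1000038T>A	172	0	0	119828
1:1000039C>G	0	119898	102	0
1:1000040T>G	0	0	119	119881
1:1000041A>G	119966	0	34	0
1:1000042T>A	113	0	0	119887
1:1000043C>A	150	119850	0	0
1:1000044T>C	0	1	0	119999
1:1000045C>G	0	119801	199	0
1:1000046T>C	0	65	0	119935
1:1000047C>G	0	119997	3	0
1:1000048C>A	176	119824	0	0
1:1000049G>T	0	0	119820	180
1:1000050A>G	119880	0	120	0
1:1000051C>A	171	119829	0	0
1:1000052G>A	50	0	119950	0
1:1000053T>C	0	187	0	119813
1:1000054T>G	0	0	164	119836
1:1000055G>T	0	0	119845	155
1:1000056A>G	119979	0	21	0
1:1000057C>G	0	119914	86	0
1:1000058G>T	0	0	119920	80
1:1000059T>G	0	0	90	119910
1:1000060T>A	182	0	0	119818
1:1000061G>C	0	82	119918	0
1:1000062G>C	0	193	119807	0
1:1000063G>A	59	0	119941	0
1:1000064G>T	0	0	119918	82
1:1000065A>G	119934	0	66	0
1:1000066A>T	119843	0	0	157
1:1000067C>A	10	119990	0	0
1:1000068G>C	0	218	119782	0
1:1000069A>T	119992	0	0	8
1:1000070A>G	119939	0	61	0
1:1000071C>A	205	119795	0	0
1:1000072G>T	0	0	119929	71
1:1000073G>A	15	0	119985	0
1:1000074G>A	158	0	119842	0
1:1000075A>T	119899	0	0	101
1:1000076C>G	0	119805	195	0
1:1000077A>C	119874	126	0	0
1:1000078C>T	0	119792	0	208
1:1000079A>C	119854	146	0	0
1:1000080A>C	119791	209	0	0
1:1000081G>C	0	181	119819	0
1:1000082C>T	0	119772	0	228
1:1000083T>C	0	97	0	119903
1:1000084A>C	119972	28	0	0
1:1000085T>A	57	0	0	119943
1:1000086T>C	0	49	0	119951
1:1000087C>A	246	119754	0	0
1:1000088A>C	119960	40	0	0
1:1000089G>A	197	0	119803	0
1:1000090A>C	119890	110	0	0
1:1000091A>G	119800	0	200	0
1:1000092C>A	159	119841	0	0
1:1000093C>A	102	119898	0	0
1:1000094T>G	0	0	166	119834
1:1000095C>T	0	119835	0	165
1:1000096A>C	119800	200	0	0
1:1000097A>T	119837	0	0	163
1:1000098A>C	119867	133	0	0
1:1000099C>A	159	119841	0	0
1:1000100G>A	16	0	119984	0
1:1000101T>G	0	0	7	119993
1:1000102A>T	119762	0	0	238
1:1000103A>T	119779	0	0	221
1:1000104C>G	0	119838	162	0
1:1000105C>A	75	119925	0	0
1:1000106A>C	119803	197	0	0
1:1000107T>G	0	0	138	119862
1:1000108C>G	0	119960	40	0
1:1000109C>G	0	119914	86	0
1:1000110G>T	0	0	119967	33
1:1000111T>C	0	133	0	119867
1:1000112A>T	119864	0	0	136
1:1000113G>T	0	0	119833	167
1:1000114G>A	63	0	119937	0
1:1000115C>G	0	119782	218	0
1:1000116G>T	0	0	119992	8
1:1000117A>T	119932	0	0	68
1:1000118G>A	234	0	119766	0
1:1000119G>C	0	92	119908	0
1:1000120G>T	0	0	119854	146
1:1000121A>G	119793	0	207	0
1:1000122G>C	0	189	119811	0
1:1000123T>C	0	39	0	119961
1:1000124C>G	0	119800	200	0
1:1000125G>A	187	0	119813	0
1:1000126A>T	119831	0	0	169
1:1000127C>T	0	119851	0	149
1:1000128C>A	117	119883	0	0
1:1000129G>A	143	0	119857	0
1:1000130A>T	119754	0	0	246
1:1000131G>A	85	0	119915	0
1:1000132G>C	0	133	119867	0
1:1000133G>C	0	192	119808	0
1:1000134G>T	0	0	119796	204
1:1000135C>G	0	119862	138	0
1:1000136G>A	113	0	119887	0
1:1000137G>A	232	0	119768	0
1:1000138C>T	0	119873	0	127
1:1000139T>G	0	0	5	119995
1:1000140C>G	0	119836	164	0
1:1000141C>G	0	119959	41	0
1:1000142A>C	119884	116	0	0
1:1000143G>T	0	0	119865	135
1:1000144T>G	0	0	154	119846
1:1000145G>C	0	92	119908	0
1:1000146A>G	119927	0	73	0
1:1000147T>C	0	150	0	119850
1:1000148T>C	0	145	0	119855
1:1000149G>A	174	0	119826	0
1:1000150T>G	0	0	213	119787
1:1000151A>G	119953	0	47	0
1:1000152G>A	152	0	119848	0
1:1000153A>G	119948	0	52	0
1:1000154T>C	0	130	0	119870
1:1000155G>T	0	0	119858	142
1:1000156G>C	0	10	119990	0
1:1000157G>T	0	0	119820	180
1:1000158A>T	119789	0	0	211
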
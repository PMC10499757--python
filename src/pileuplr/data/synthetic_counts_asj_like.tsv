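# synthetic stand-in fixture: generator output at seed 20221024
# 159 biallelic loci, founder-enriched ASJ-like vs NFE-like tallies
locus_id	A	C	G	T
1:1000000C>A	178	9822	0	0
1:1000001C>G	0	9964	36	0
1:1000002T>C	0	211	0	9789
1:1000003A>C	9838	162	0	0
1:1000004A>G	9972	0	28	0
1:1000005A>G	9872	0	128	0
1:1000006T>A	148	0	0	9852
1:1000007C>A	127	9873	0	0
1:1000008T>C	0	29	0	9971
1:1000009T>G	0	0	236	9764
1:1000010C>T	0	9812	0	188
1:1000011T>G	0	0	71	9929
1:1000012A>G	9853	0	147	0
1:1000013A>T	9962	0	0	38
1:1000014G>T	0	0	9867	133
1:1000015G>T	0	0	9959	41
1:1000016A>T	9898	0	0	102
1:1000017G>A	54	0	9946	0
1:1000018C>A	170	9830	0	0
1:1000019T>A	22	0	0	9978
1:1000020A>T	9899	0	0	101
1:1000021T>C	0	112	0	9888
1:1000022G>C	0	99	9901	0
1:1000023T>C	0	36	0	9964
1:1000024A>T	9796	0	0	204
1:1000025A>G	9843	0	157	0
1:1000026A>T	9873	0	0	127
1:1000027T>C	0	92	0	9908
1:1000028G>T	0	0	9827	173
1:1000029G>T	0	0	9857	143
1:1000030A>C	9975	25	0	0
1:1000031A>T	9810	0	0	190
1:1000032A>C	9809	191	0	0
1:1000033A>G	9845	0	155	0
1:1000034C>T	0	9821	0	179
1:1000035A>T	9865	0	0	135
1:1000036T>C	0	135	0	9865
1:1000037G>C	0	108	9892	0
1:1000038T>A	43	0	0	9957
1:1000039C>G	0	9873	127	0
1:1000040T>G	0	0	112	9888
1:1000041A>G	9778	0	222	0
1:1000042T>A	22	0	0	9978
1:1000043C>A	74	9926	0	0
1:1000044T>C	0	85	0	9915
1:1000045C>G	0	9944	56	0
1:1000046T>C	0	54	0	9946
1:1000047C>G	0	9929	71	0
1:1000048C>A	99	9901	0	0
1:1000049G>T	0	0	9842	158
1:1000050A>G	9914	0	86	0
1:1000051C>A	116	9884	0	0
1:1000052G>A	134	0	9866	0
1:1000053T>C	0	24	0	9976
1:1000054T>G	0	0	35	9965
1:1000055G>T	0	0	9847	153
1:1000056A>G	9910	0	90	0
1:1000057C>G	0	9970	30	0
1:1000058G>T	0	0	9814	186
1:1000059T>G	0	0	74	9926
1:1000060T>A	86	0	0	9914
1:1000061G>C	0	137	9863	0
1:1000062G>C	0	36	9964	0
1:1000063G>A	84	0	9916	0
1:1000064G>T	0	0	9953	47
1:1000065A>G	9811	0	189	0
1:1000066A>T	9959	0	0	41
1:1000067C>A	87	9913	0	0
1:1000068G>C	0	110	9890	0
1:1000069A>T	9819	0	0	181
1:1000070A>G	9848	0	152	0
1:1000071C>A	106	9894	0	0
1:1000072G>T	0	0	9886	114
1:1000073G>A	169	0	9831	0
1:1000074G>A	97	0	9903	0
1:1000075A>T	9781	0	0	219
1:1000076C>G	0	9859	141	0
1:1000077A>C	9909	91	0	0
1:1000078C>T	0	9844	0	156
1:1000079A>C	9962	38	0	0
1:1000080A>C	9905	95	0	0
1:1000081G>C	0	110	9890	0
1:1000082C>T	0	9834	0	166
1:1000083T>C	0	54	0	9946
1:1000084A>C	9932	68	0	0
1:1000085T>A	173	0	0	9827
1:1000086T>C	0	131	0	9869
1:1000087C>A	47	9953	0	0
1:1000088A>C	9855	145	0	0
1:1000089G>A	129	0	9871	0
1:1000090A>C	9829	171	0	0
1:1000091A>G	9944	0	56	0
1:1000092C>A	138	9862	0	0
1:1000093C>A	71	9929	0	0
1:1000094T>G	0	0	158	9842
1:1000095C>T	0	9772	0	228
1:1000096A>C	9919	81	0	0
1:1000097A>T	9885	0	0	115
1:1000098A>C	9862	138	0	0
1:1000099C>A	84	9916	0	0
1:1000100G>A	136	0	9864	0
1:1000101T>G	0	0	58	9942
1:1000102A>T	9814	0	0	186
1:1000103A>T	9866	0	0	134
1:1000104C>G	0	9980	20	0
1:1000105C>A	144	9856	0	0
1:1000106A>C	9958	42	0	0
1:1000107T>G	0	0	101	9899
1:1000108C>G	0	9961	39	0
1:1000109C>G	0	9836	164	0
1:1000110G>T	0	0	9860	140
1:1000111T>C	0	15	0	9985
1:1000112A>T	9794	0	0	206
1:1000113G>T	0	0	9932	68
1:1000114G>A	152	0	9848	0
1:1000115C>G	0	9953	47	0
1:1000116G>T	0	0	9844	156
1:1000117A>T	9942	0	0	58
1:1000118G>A	71	0	9929	0
1:1000119G>C	0	156	9844	0
1:1000120G>T	0	0	9896	104
1:1000121A>G	9890	0	110	0
1:1000122G>C	0	197	9803	0
1:1000123T>C	0	20	0	9980
1:1000124C>G	0	9852	148	0
1:1000125G>A	62	0	9938	0
1:1000126A>T	9929	0	0	71
1:1000127C>T	0	9873	0	127
1:1000128C>A	52	9948	0	0
1:1000129G>A	42	0	9958	0
1:1000130A>T	9898	0	0	102
1:1000131G>A	46	0	9954	0
1:1000132G>C	0	157	9843	0
1:1000133G>C	0	27	9973	0
1:1000134G>T	0	0	9849	151
1:1000135C>G	0	9954	46	0
1:1000136G>A	54	0	9946	0
1:1000137G>A	162	0	9838	0
1:1000138C>T	0	9872	0	128
1:1000139T>G	0	0	37	9963
1:1000140C>G	0	9939	61	0
1:1000141C>G	0	9911	89	0
1:1000142A>C	9954	46	0	0
1:1000143G>T	0	0	9851	149
1:1000144T>G	0	0	135	9865
1:1000145G>C	0	183	9817	0
1:1000146A>G	9843	0	157	0
1:1000147T>C	0	68	0	9932
1:1000148T>C	0	176	0	9824
1:1000149G>A	137	0	9863	0
1:1000150T>G	0	0	180	9820
1:1000151A>G	9904	0	96	0
1:1000152G>A	93	0	9907	0
1:1000153A>G	9783	0	217	0
1:1000154T>C	0	201	0	9799
1:1000155G>T	0	0	9898	102
1:1000156G>C	0	60	9940	0
1:1000157G>T	0	0	9896	104
1:1000158A>T	9957	0	0	43
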
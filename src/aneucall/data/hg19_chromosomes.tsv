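chrom	length	centromere
1	249250621	123035434
2	243199373	93826171
3	198022430	92004854
4	191154276	51160117
5	180915260	47905641
6	171115067	60330166
7	159138663	59554331
8	146364022	45338887
9	141213431	48867679
10	135534747	40754935
11	135006516	53144205
12	133851895	36356694
13	115169878	17500000
14	107349540	17500000
15	102531392	18500000
16	90354753	36835801
17	81195210	23763006
18	78077248	16960898
19	59128983	26181782
20	63025520	27869569
21	48129895	12788129
22	51304566	14500000
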
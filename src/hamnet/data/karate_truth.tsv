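# Two-faction split of the Zachary karate club, benchmark convention:
# the weakly-affiliated actor 8 is grouped with the officers' faction,
# giving the maximum-modularity two-community split (Q = 0.3715).
0	0
1	0
2	0
3	0
4	0
5	0
6	0
7	0
8	1
9	1
10	0
11	0
12	0
13	0
14	1
15	1
16	0
17	0
18	1
19	0
20	1
21	0
22	1
23	1
24	1
25	1
26	1
27	1
28	1
29	1
30	1
31	1
32	1
33	1
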
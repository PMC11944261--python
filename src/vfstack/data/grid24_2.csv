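index,x,y,is_blind_spot,is_edge,hemifield,sector
1,9,21,0,1,superior,ST
2,3,21,0,1,superior,ST
3,-3,21,0,1,superior,SN
4,-9,21,0,1,superior,SN
5,15,15,0,1,superior,ST
6,9,15,0,0,superior,ST
7,3,15,0,0,superior,ST
8,-3,15,0,0,superior,SN
9,-9,15,0,0,superior,SN
10,-15,15,0,1,superior,SN
11,21,9,0,1,superior,ST
12,15,9,0,1,superior,ST
13,9,9,0,0,superior,ST
14,3,9,0,0,superior,ST
15,-3,9,0,0,superior,SN
16,-9,9,0,0,superior,SN
17,-15,9,0,0,superior,SN
18,-21,9,0,1,superior,SN
19,21,3,0,1,superior,T
20,15,3,1,1,superior,T
21,9,3,0,0,superior,central
22,3,3,0,0,superior,central
23,-3,3,0,0,superior,central
24,-9,3,0,0,superior,central
25,-15,3,0,0,superior,SN
26,-21,3,0,0,superior,N
27,-27,3,0,1,superior,N
28,21,-3,0,1,inferior,T
29,15,-3,1,1,inferior,T
30,9,-3,0,0,inferior,central
31,3,-3,0,0,inferior,central
32,-3,-3,0,0,inferior,central
33,-9,-3,0,0,inferior,central
34,-15,-3,0,0,inferior,IN
35,-21,-3,0,0,inferior,N
36,-27,-3,0,1,inferior,N
37,21,-9,0,1,inferior,IT
38,15,-9,0,1,inferior,IT
39,9,-9,0,0,inferior,IT
40,3,-9,0,0,inferior,IT
41,-3,-9,0,0,inferior,IN
42,-9,-9,0,0,inferior,IN
43,-15,-9,0,0,inferior,IN
44,-21,-9,0,1,inferior,IN
45,15,-15,0,1,inferior,IT
46,9,-15,0,0,inferior,IT
47,3,-15,0,0,inferior,IT
48,-3,-15,0,0,inferior,IN
49,-9,-15,0,0,inferior,IN
50,-15,-15,0,1,inferior,IN
51,9,-21,0,1,inferior,IT
52,3,-21,0,1,inferior,IT
53,-3,-21,0,1,inferior,IN
54,-9,-21,0,1,inferior,IN
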
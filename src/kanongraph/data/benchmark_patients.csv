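id,Gender,Age,Zip code,Marriage,Smoke,Diagnosis
1,F,56,33613,Divorce,Y,AA
2,F,60,33647,Marriage,N,Diabetes
3,M,81,34660,Single,N,AA
4,M,44,32801,Divorce,Y,AA
5,M,56,32211,Marriage,N,AA
6,M,34,32868,Marriage,N,Normal
7,F,73,34768,Single,N,AA
8,M,77,33102,Marriage,N,AA
9,F,84,32855,Single,N,AA
10,F,68,33709,Marriage,N,ACML
11,F,66,34302,Marriage,Y,Diabetes
12,M,53,34565,Single,Y,AML
13,M,59,32652,Marriage,Y,AITCL
14,F,63,33615,Marriage,N,Normal
15,F,19,75865,Single,N,AML
16,M,38,33650,Single,Y,Normal
17,M,56,75677,Marriage,N,Normal
18,F,67,33218,Marriage,N,AA
19,M,65,34813,Marriage,N,ACML
20,M,71,32556,Marriage,N,Normal
21,F,67,33451,Marriage,Y,AML FROM MDS
22,M,60,33648,Marriage,Y,Normal
23,F,56,33613,Divorce,N,AA
24,F,60,33647,Marriage,Y,AA
25,M,51,34660,Single,N,ACML
26,M,34,32801,Divorce,N,Normal
27,M,56,32211,Marriage,N,AML FROM MDS
28,M,34,32868,Marriage,Y,ACML
29,M,38,72868,Marriage,N,ACML
30,F,73,34768,Single,N,AA
31,F,57,33102,Marriage,N,AA
32,F,84,32855,Single,N,AA
33,F,60,33709,Marriage,N,Diabetes
34,F,66,34302,Marriage,Y,ACML
35,M,73,34565,Single,N,AML
36,M,59,32652,Marriage,N,AITCL
37,F,43,33615,Marriage,Y,AML
38,F,29,75865,Single,Y,AML
39,M,48,33650,Single,N,AML
40,M,76,75677,Marriage,N,Normal
41,F,37,33218,Marriage,Y,AML
42,M,45,34813,Marriage,N,AML
43,M,51,32556,Marriage,N,AITCL
44,F,67,33451,Marriage,N,AML
45,M,60,33648,Marriage,N,Normal
46,F,56,33613,Divorce,Y,AA
47,F,63,33647,Marriage,N,AA
48,M,56,34660,Marriage,N,Normal
49,M,34,32801,Divorce,Y,AML
50,M,52,32211,Marriage,N,AITCL
51,M,34,32868,Marriage,N,Normal
52,F,43,34768,Single,Y,AA
53,M,38,75685,Marriage,Y,AML FROM MDS
54,M,42,72512,Marriage,Y,ACML
55,M,26,75828,Single,Y,ACML
56,F,33,34574,Single,N,AA
57,M,47,34543,Marriage,Y,ACML
58,F,62,32767,Marriage,Y,Normal
59,M,55,75926,Marriage,Y,AML
60,M,42,75384,Marriage,Y,AML
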
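k,0,0.2,0.4,0.6,0.8,1
3,0.156685,0.150157,0.150157,0.150157,0.150157,0.184306
6,0.182498,0.182172,0.182172,0.182172,0.182097,0.205461
9,0.18415,0.188338,0.188338,0.188338,0.188031,0.208391
12,0.192364,0.19258,0.192517,0.195209,0.196268,0.209272
15,0.195478,0.195952,0.195952,0.197481,0.195349,0.210337
18,0.198426,0.198426,0.198426,0.198426,0.198616,0.210719
21,0.200807,0.200807,0.200807,0.200807,0.201999,0.210436
24,0.204509,0.204509,0.204509,0.204509,0.201373,0.210497
27,0.204427,0.204427,0.204427,0.204427,0.204442,0.211029
30,0.205762,0.205762,0.205762,0.205762,0.207728,0.211137
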
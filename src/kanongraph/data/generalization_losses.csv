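k,0,0.2,0.4,0.6,0.8,1
3,0.278462,0.240051,0.240051,0.240051,0.240051,0.118513
6,0.242615,0.22241,0.22241,0.22241,0.224,0.140103
9,0.211692,0.216103,0.216103,0.216103,0.213051,0.127205
12,0.211026,0.213744,0.209615,0.195641,0.190718,0.124282
15,0.202949,0.215513,0.215513,0.204872,0.207949,0.135513
18,0.214872,0.214872,0.214872,0.214872,0.198615,0.123538
21,0.200333,0.200333,0.200333,0.200333,0.196923,0.116333
24,0.203256,0.203256,0.203256,0.203256,0.192,0.12141
27,0.201795,0.201795,0.201795,0.201795,0.202949,0.134615
30,0.206667,0.206667,0.206667,0.206667,0.197308,0.152821
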
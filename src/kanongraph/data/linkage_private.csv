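ID,Zip code,Age,Disease
1,273212,33,heart disease
2,273215,45,heart disease
3,273203,23,influenza
4,273211,29,heart disease
5,273207,50,cancer
6,273206,20,influenza
7,273221,31,A-dis
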
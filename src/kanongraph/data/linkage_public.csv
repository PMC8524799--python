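ID,Name,Gender,Zip code,Age
1,Mary,Male,273209,29
2,Alice,Female,273212,33
3,David,Male,273211,29
4,Sam,Female,273207,50
5,Joan,Male,273206,20
6,Angle,Female,273221,31
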
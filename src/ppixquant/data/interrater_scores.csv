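standard,NS1,NS2,MS1,MS2
1,4,4,4,4
2,4,4,4,4
3,3,4,3,4
4,3,4,3,3
5,3,3,3,3
6,2,2,2,2
7,2,2,2,2
8,1,1,2,1
9,1,1,1,1
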
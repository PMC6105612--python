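score,definition
0,No fluorescence
1,Minimal fluorescence
2,Moderate fluorescence
3,High fluorescence
4,Very high fluorescence
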
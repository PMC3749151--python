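group,pair,value
TT1,1 and 5,33
TT1,2 and 5,30
TT1,2 and 1,30
TT1,6 and 1,25
TT1,6 and 5,22
TT1,6 and 2,22
TT2,9 and 8,50
TT2,4 and 9,39
TT2,7 and 9,36
TT2,3 and 9,36
TT2,7 and 8,31
TT2,3 and 8,28
TT2,7 and 4,28
TT2,4 and 8,28
TT2,3 and 7,25
TT2,3 and 4,25
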
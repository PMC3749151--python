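participant,task,score
1,locating,80
2,locating,67
3,locating,72
5,locating,80
7,locating,69
1,diagnosing,44
2,diagnosing,42
3,diagnosing,39
5,diagnosing,47
7,diagnosing,36
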
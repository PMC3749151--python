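block,pair,task,abrasion,value
hand_lens,2 and 1,locating,included,64
hand_lens,2 and 5,locating,included,61
hand_lens,2 and 3,locating,included,61
hand_lens,2 and 7,locating,included,56
hand_lens,1 and 5,locating,included,67
hand_lens,1 and 3,locating,included,69
hand_lens,1 and 7,locating,included,67
hand_lens,3 and 7,locating,included,58
hand_lens,3 and 5,locating,included,64
hand_lens,7 and 5,locating,included,58
hand_lens,2 and 1,locating,excluded,63
hand_lens,2 and 5,locating,excluded,59
hand_lens,2 and 3,locating,excluded,60
hand_lens,2 and 7,locating,excluded,56
hand_lens,1 and 5,locating,excluded,70
hand_lens,1 and 3,locating,excluded,71
hand_lens,1 and 7,locating,excluded,71
hand_lens,3 and 7,locating,excluded,60
hand_lens,3 and 5,locating,excluded,63
hand_lens,7 and 5,locating,excluded,63
hand_lens,2 and 1,diagnosing,included,30
hand_lens,2 and 5,diagnosing,included,30
hand_lens,2 and 3,diagnosing,included,28
hand_lens,2 and 7,diagnosing,included,25
hand_lens,1 and 5,diagnosing,included,33
hand_lens,1 and 3,diagnosing,included,25
hand_lens,1 and 7,diagnosing,included,31
hand_lens,3 and 7,diagnosing,included,25
hand_lens,3 and 5,diagnosing,included,25
hand_lens,7 and 5,diagnosing,included,25
hand_lens,2 and 1,diagnosing,excluded,41
hand_lens,2 and 5,diagnosing,excluded,41
hand_lens,2 and 3,diagnosing,excluded,37
hand_lens,2 and 7,diagnosing,excluded,33
hand_lens,1 and 5,diagnosing,excluded,44
hand_lens,1 and 3,diagnosing,excluded,33
hand_lens,1 and 7,diagnosing,excluded,41
hand_lens,3 and 7,diagnosing,excluded,33
hand_lens,3 and 5,diagnosing,excluded,33
hand_lens,7 and 5,diagnosing,excluded,33
microscope,4 and 6,locating,included,58
microscope,6 and 9,locating,included,78
microscope,6 and 8,locating,included,75
microscope,4 and 9,locating,included,67
microscope,4 and 8,locating,included,67
microscope,9 and 8,locating,included,92
microscope,4 and 6,locating,excluded,63
microscope,6 and 9,locating,excluded,78
microscope,6 and 8,locating,excluded,78
microscope,4 and 9,locating,excluded,74
microscope,4 and 8,locating,excluded,74
microscope,9 and 8,locating,excluded,99
microscope,4 and 6,diagnosing,included,25
microscope,6 and 9,diagnosing,included,42
microscope,6 and 8,diagnosing,included,28
microscope,4 and 9,diagnosing,included,44
microscope,4 and 8,diagnosing,included,28
microscope,9 and 8,diagnosing,included,56
microscope,4 and 6,diagnosing,excluded,33
microscope,6 and 9,diagnosing,excluded,48
microscope,6 and 8,diagnosing,excluded,37
microscope,4 and 9,diagnosing,excluded,48
microscope,4 and 8,diagnosing,excluded,37
microscope,9 and 8,diagnosing,excluded,67
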
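experiment,live_weight_kg,strokes_filleting,strokes_defleshing_head,time_filleting_min,time_defleshing_head_min
6,6,529,622,8,11
7,7.2,855,702,10,15
9,3.2,848,454,11,9
11,4.5,608,470,7.3,7
12,2,708,240,11,4.3
13,4,1170,430,14,6
15,2.1,350,180,10,10
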
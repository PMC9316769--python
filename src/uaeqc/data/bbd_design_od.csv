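run_id,methanol,ratio,time,coded_methanol,coded_ratio,coded_time,od
1,50,30,35,-1,-1,0,0.4249
2,90,30,35,1,-1,0,0.0
3,50,70,35,-1,1,0,0.87
4,90,70,35,1,1,0,0.4947
5,50,50,20,-1,0,-1,0.6189
6,90,50,20,1,0,-1,0.0
7,50,50,50,-1,0,1,0.6671
8,90,50,50,1,0,1,0.3522
9,70,30,20,0,-1,-1,0.4575
10,70,70,20,0,1,-1,0.8231
11,70,30,50,0,-1,1,0.6224
12,70,70,50,0,1,1,0.9318
13,70,50,35,0,0,0,0.8038
14,70,50,35,0,0,0,0.8591
15,70,50,35,0,0,0,0.7822
16,70,50,35,0,0,0,0.803
17,70,50,35,0,0,0,0.7969
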
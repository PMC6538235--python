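collimator_mm,depth_mm,side,penumbra_mm
4,50,left,1.77
5,50,left,1.88
7.5,50,left,1.94
10,50,left,2.00
12.5,50,left,2.06
15,50,left,2.11
20,50,left,2.19
25,50,left,2.27
4,100,left,2.00
5,100,left,2.12
7.5,100,left,2.21
10,100,left,2.29
12.5,100,left,2.35
15,100,left,2.43
20,100,left,2.54
25,100,left,2.64
4,50,right,1.78
5,50,right,1.85
7.5,50,right,1.93
10,50,right,1.99
12.5,50,right,2.08
15,50,right,2.11
20,50,right,2.19
25,50,right,2.27
4,100,right,2.02
5,100,right,2.11
7.5,100,right,2.19
10,100,right,2.28
12.5,100,right,2.39
15,100,right,2.44
20,100,right,2.53
25,100,right,2.69
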
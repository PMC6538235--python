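station,description,beam_position,rate_mr_per_hr,use_factor,duty_cycle
1,Foot End Table Shield,G=45,3.0,0.2,0.078
2,Right Side Main Gantry,G=45,0.09,0.2,0.078
3,Left Side Main Gantry,G=90,0.1,0.2,0.078
4,Head End of System,G=45,0.36,0.2,0.078
5,Table Right,G=90,0.45,0.2,0.078
6,Table - Orbit Right,G=90,0.37,0.2,0.078
7,Right Gantry,G=0,0.19,0.2,0.078
8,Right Gantry,G=270,1.72,0.2,0.078
9,Right - Head,G=45,2.70,0.2,0.078
10,Left - Head,G=45,2.80,0.2,0.078
11,Left Gantry,G=45,1.70,0.2,0.078
12,Left Gantry,G=0,0.57,0.2,0.078
13,Table - Orbit Left,G=0,0.84,0.2,0.078
14,Table Left,G=0,0.4,0.2,0.078
15,Control Console,G=0,0.11,0.2,0.078
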
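pair,kind,p_value
1,max_slope,0.657721015
1,min_slope,0.936337338
1,plateau_begin,0.417005168
1,plateau_end,0.986805014
2,max_slope,0.010577057
2,min_slope,0.064029034
2,plateau_begin,0.097578139
2,plateau_end,0.317799703
3,max_slope,0.000196868
3,min_slope,0.303675632
3,plateau_begin,0.066103149
3,plateau_end,0.019539292
4,max_slope,2.66550e-19
4,min_slope,4.10299e-06
4,plateau_begin,2.01957e-15
4,plateau_end,0.000686408
5,max_slope,7.86896e-19
5,min_slope,9.69148e-05
5,plateau_begin,2.93382e-15
5,plateau_end,0.001116038
6,max_slope,2.92339e-26
6,min_slope,8.04271e-09
6,plateau_begin,8.07804e-27
6,plateau_end,3.30665e-15
7,max_slope,0.729215365
7,min_slope,0.637028887
7,plateau_begin,0.841677533
7,plateau_end,0.687908256
8,max_slope,0.734146578
8,min_slope,0.411370955
8,plateau_begin,0.302637642
8,plateau_end,0.819808126
9,max_slope,6.67436e-05
9,min_slope,0.263113108
9,plateau_begin,0.006803160
9,plateau_end,0.000531943
10,max_slope,0.665538015
10,min_slope,0.024729645
10,plateau_begin,0.976871651
10,plateau_end,0.131110278
11,max_slope,0.018054682
11,min_slope,0.002703960
11,plateau_begin,0.285120361
11,plateau_end,0.004076710
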
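model,d_sa_mm,a_lt_deg,r_tt_mm,delta_p_mmhg
1,10,20,5,3.27
2,10,10,2.5,5.36
3,15,20,0,6.79
4,20,0,2.5,8.23
5,25,20,2.5,5.6
6,20,40,0,2.88
7,20,20,7.5,3.47
8,25,30,5,2.75
9,30,30,0,8.34
10,15,30,2.5,2.77
11,20,30,10,2.19
12,25,0,10,4.56
13,30,10,7.5,4.43
14,30,20,10,3.25
15,15,40,5,1.49
16,30,40,2.5,1.75
17,10,30,7.5,1.77
18,10,40,10,1.1
19,10,0,0,8.26
20,25,40,7.5,1.23
21,30,0,5,6.6
22,15,10,10,3.89
23,20,10,5,5.13
24,25,10,0,12.91
25,15,0,7.5,5.11
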
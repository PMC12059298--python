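number,tube_current_ma,indoqct_mtf50_lp_cm,indoqct_mtf10_lp_cm,single_mtf50_lp_cm,single_mtf10_lp_cm
1,611,3.5,5.9,3.36,6.17
2,612,4.5,7.9,4.21,7.67
3,612,4.5,8.9,4.16,7.89
4,613,5.2,8.3,4.67,8.66
5,614,4.5,7.5,4.1,7.55
6,615,3.4,6.6,3.52,6.46
7,615,4.6,7.6,4.33,7.91
8,615,5.0,6.6,4.37,7.95
9,615,5.2,8.5,4.83,8.79
10,616,5.2,8.0,4.72,8.57
11,616,5.3,8.2,4.77,8.93
12,617,5.2,8.6,3.96,7.34
13,618,4.9,9.0,3.8,7.13
14,618,5.3,8.9,5.27,9.54
15,618,5.8,9.3,4.74,8.67
16,619,4.5,6.5,3.99,7.28
17,620,5.4,9.6,5.34,9.66
18,620,5.8,9.8,5.38,9.73
19,621,5.6,8.5,5.07,9.18
20,622,5.7,9.8,5.14,9.3
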
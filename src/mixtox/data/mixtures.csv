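combo_id,printed_no,component_a,component_b,ratio,neg_log_ec50mix_exp,mlr_pred,mlr_residual,rbfnn_pred,rbfnn_residual,subset
1,1,1#,14#,1:1,2.44,2.36,-0.08,2.67,0.23,A
2,2,2#,14#,1:1,2.63,2.38,-0.25,2.68,0.05,B
3,3,3#,14#,1:1,2.77,2.38,-0.39,2.69,-0.08,T
4,4,4#,14#,1:1,2.78,2.61,-0.17,2.77,-0.01,C
5,5,5#,14#,1:1,2.8,3.14,0.34,2.79,-0.01,D
6,6,6#,14#,1:1,2.84,2.61,-0.23,2.80,-0.04,A
7,7,7#,14#,1:1,2.84,3.33,0.49,2.70,-0.14,B
8,8,8#,14#,1:1,2.83,2.75,-0.08,2.82,-0.01,T
9,9,9#,14#,1:1,2.84,2.75,-0.09,2.81,-0.03,C
10,10,10#,14#,1:1,2.85,2.70,-0.15,2.81,-0.04,D
11,11,11#,14#,1:1,2.83,2.84,0.01,2.82,-0.01,A
12,12,12#,14#,1:1,2.84,2.82,-0.02,2.82,-0.02,B
13,13,13#,14#,1:1,2.85,3.18,0.33,2.78,-0.07,T
14,14,5#,15#,1:1,3.15,3.25,0.10,3.03,-0.12,C
15,15,6#,15#,1:1,3.26,2.72,-0.54,3.21,-0.05,D
16,16,7#,15#,1:1,3.25,3.44,0.19,3.17,-0.08,A
17,17,8#,15#,1:1,3.24,2.86,-0.38,3.11,-0.13,B
18,18,9#,15#,1:1,3.26,2.85,-0.41,3.10,-0.16,T
19,19,10#,15#,1:1,3.27,2.80,-0.47,3.14,-0.13,C
20,20,11#,15#,1:1,3.22,2.95,-0.27,3.02,-0.20,D
21,21,13#,15#,1:1,3.28,3.29,0.01,3.06,-0.22,A
22,22,1#,16#,1:1,2.64,3.43,0.79,3.38,0.74,B
23,23,2#,16#,1:1,2.97,3.45,0.48,3.38,0.41,T
24,24,3#,16#,1:1,3.39,3.46,0.07,3.38,-0.01,C
25,25,5#,16#,1:1,3.51,4.22,0.71,3.71,0.20,D
26,26,6#,16#,1:1,3.83,3.70,-0.13,3.42,-0.41,A
27,27,7#,16#,1:1,3.78,4.41,0.63,3.52,-0.26,B
28,28,8#,16#,1:1,3.75,3.83,0.08,3.56,-0.19,T
29,29,9#,16#,1:1,3.83,3.82,-0.01,3.56,-0.27,C
30,30,10#,16#,1:1,3.86,3.78,-0.08,3.51,-0.35,D
31,31,11#,16#,1:1,3.7,3.92,0.22,3.67,-0.03,A
32,32,12#,16#,1:1,3.77,3.90,0.13,3.61,-0.16,B
33,33,13#,16#,1:1,3.9,4.26,0.36,3.68,-0.22,T
34,34,1#,17#,1:1,2.18,2.10,-0.08,1.81,-0.37,C
35,35,3#,17#,1:1,2.33,2.13,-0.20,1.87,-0.46,D
36,36,4#,17#,1:1,2.34,2.35,0.01,1.93,-0.41,A
37,37,5#,17#,1:1,2.34,2.89,0.55,2.68,0.34,B
38,38,6#,17#,1:1,2.36,2.36,0.00,2.28,-0.08,T
39,39,7#,17#,1:1,2.36,3.07,0.71,3.06,0.70,C
40,40,8#,17#,1:1,2.36,2.50,0.14,2.27,-0.09,D
41,41,10#,17#,1:1,2.36,2.44,0.08,2.25,-0.11,A
42,42,11#,17#,1:1,2.35,2.59,0.24,2.27,-0.08,B
43,43,12#,17#,1:1,2.35,2.56,0.21,2.28,-0.07,T
44,44,13#,17#,1:1,2.36,2.93,0.57,2.74,0.38,C
45,45,5#,18#,1:1,3.45,4.01,0.56,4.06,0.61,D
46,46,6#,18#,1:1,3.72,3.48,-0.24,3.53,-0.19,A
47,47,7#,18#,1:1,3.68,4.19,0.51,3.88,0.20,B
48,48,8#,18#,1:1,3.66,3.62,-0.04,3.76,0.10,T
49,49,10#,18#,1:1,3.74,3.56,-0.18,3.68,-0.06,C
50,50,11#,18#,1:1,3.62,3.71,0.09,3.94,0.32,D
51,51,12#,18#,1:1,3.67,3.68,0.01,3.86,0.19,A
52,52,13#,18#,1:1,3.78,4.05,0.27,4.03,0.25,B
53,53,5#,19#,1:1,3.67,3.72,0.05,4.23,0.56,T
54,54,6#,19#,1:1,4.25,3.20,-1.05,3.25,-1.00,C
55,55,7#,19#,1:1,4.14,3.91,-0.23,4.23,0.09,D
56,56,8#,19#,1:1,4.08,3.34,-0.74,3.56,-0.52,A
57,67,9#,19#,1:1,4.26,3.33,-0.93,3.56,-0.70,B
58,58,10#,19#,1:1,4.36,3.28,-1.08,3.45,-0.91,T
59,59,13#,19#,1:1,4.5,3.76,-0.74,4.23,-0.27,C
60,60,25#,35#,1:1,6.94,7.10,0.16,7.78,0.84,D
61,61,25#,36#,1:1,6.97,7.01,0.04,7.63,0.66,A
62,62,25#,37#,1:1,6.89,7.28,0.39,6.95,0.06,B
63,63,25#,38#,1:1,6.45,7.21,0.76,7.92,1.47,T
64,64,26#,35#,1:1,7.86,6.48,-1.38,6.76,-1.10,C
65,65,26#,36#,1:1,8.2,6.39,-1.81,6.90,-1.30,D
66,66,26#,37#,1:1,7.56,6.67,-0.89,7.64,0.08,A
67,67,26#,38#,1:1,6.59,6.60,0.01,6.45,-0.14,B
68,68,27#,35#,1:1,6.58,5.97,-0.61,6.95,0.37,T
69,69,27#,36#,1:1,6.59,5.88,-0.71,6.81,0.22,C
70,70,27#,37#,1:1,6.55,6.16,-0.39,7.10,0.55,D
71,71,27#,38#,1:1,6.29,6.08,-0.21,7.03,0.74,A
72,72,28#,35#,1:1,8,7.25,-0.75,7.64,-0.36,B
73,73,28#,36#,1:1,8.6,7.15,-1.45,7.79,-0.81,T
74,74,28#,37#,1:1,7.62,7.43,-0.19,7.90,0.28,C
75,75,28#,38#,1:1,6.6,7.36,0.76,7.31,0.71,D
76,76,29#,35#,1:1,5.73,6.73,1.00,6.12,0.39,A
77,77,29#,36#,1:1,5.73,6.64,0.91,6.38,0.65,B
78,78,29#,37#,1:1,5.73,6.92,1.19,7.29,1.56,T
79,79,29#,38#,1:1,5.68,6.85,1.17,5.67,-0.01,C
80,80,45#,55#,1:1,5.08,5.45,0.37,5.86,0.78,D
81,81,46#,55#,1:1,4.85,4.26,-0.59,3.98,-0.87,A
82,82,47#,55#,1:1,5.5,4.89,-0.61,5.02,-0.48,B
83,83,48#,55#,1:1,5.42,5.17,-0.25,5.56,0.14,T
84,84,49#,55#,1:1,5.45,5.45,0.00,6.06,0.61,C
85,85,50#,55#,1:1,6.01,4.90,-1.11,5.05,-0.96,D
86,86,51#,55#,1:1,5.73,5.23,-0.50,5.56,-0.17,A
87,87,47#,55#,13396:1,3.49,4.48,0.99,3.84,0.35,B
88,88,47#,55#,8587:1,3.49,4.48,0.99,3.84,0.35,T
89,89,47#,55#,2747:1,3.49,4.48,0.99,3.84,0.35,C
90,90,47#,55#,858:1,3.51,4.48,0.97,3.84,0.33,D
91,91,47#,55#,274:1,3.55,4.49,0.94,3.85,0.30,A
92,92,47#,55#,85:1,3.67,4.49,0.82,3.86,0.19,B
93,93,47#,55#,27:1,3.92,4.51,0.59,3.92,0.00,T
94,94,47#,55#,15:1,4.08,4.53,0.45,3.98,-0.10,C
95,95,47#,55#,4:1,4.52,4.64,0.12,4.32,-0.20,D
96,96,47#,55#,1:6,5.34,4.59,-0.75,4.18,-1.16,A
97,97,47#,55#,1:21,5.43,5.25,-0.18,5.37,-0.06,B
98,98,47#,55#,1:37,5.45,5.27,-0.18,5.36,-0.09,T
99,99,47#,55#,1:116,5.46,5.28,-0.18,5.34,-0.12,C
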
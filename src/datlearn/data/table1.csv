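subject_id,age,sex,updrs_iii_total,ues,sbr_caudate,sbr_putamen,z_caudate,z_putamen,ledd,diagnosis
1,47,F,24,10,1.88,1.09,-4.22,-5.45,0,PD
2,62,M,30,11,2.1,1.15,-2.98,-4.87,52,PD
3,69,M,3,0,2.72,2.61,-1.32,-0.77,0,RBD
4,64,F,23,6,2.74,2.93,-1.27,-0.24,0,PD
5,57,F,27,11,1.58,1.13,-4.52,-5.18,150,PD
6,70,M,38,7,3.05,2.3,-0.45,-1.52,300,PD
7,72,M,12,2,2.3,2.11,-1.78,-1.6,0,ET
8,56,M,10,1,2.09,1.81,-2.46,-2.64,0,ET
9,75,F,20,8,1.22,0.81,-3.63,-4.1,250,PD
10,64,M,27,9,1.29,0.78,-3.97,-4.56,0,PD
11,53,M,16,5,2.08,1.91,-2.72,-2.54,0,ET
12,61,M,17,5,1.35,0.8,-3.74,-4.49,0,PD
13,73,F,4,0,2.69,2.74,-0.86,-0.36,50,ET
14,46,M,6,0,2.44,2.02,-2.06,-2.5,0,ET
15,60,M,36,11,1.4,1.3,-3.88,-3.63,100,PD
16,63,M,12,4,1.99,1.7,-2.48,-2.67,0,PD
17,54,M,35,9,1.71,1.52,-3.41,-3.32,0,PD
18,74,M,30,6,1.55,1.22,-3.19,-3.37,300,PD
19,58,M,12,3,1.32,0.91,-4.07,-4.47,105,PD
20,75,M,32,8,1.51,0.89,-3.07,-3.94,0,PD
21,68,F,37,9,1.78,1.02,-2.9,-3.95,0,PD
22,52,F,17,1,3.23,2.83,-0.52,-0.68,0,ET
23,65,M,18,6,1.44,0.86,-3.64,-4.37,0,PD
24,72,F,8,2,3.05,3.04,-0.32,-0.32,0,ET
25,72,M,36,10,1.21,0.83,-3.92,-4.24,300,PD
26,68,M,15,6,1.52,1.22,-3.41,-3.55,0,PD
27,72,F,9,2,2.25,2.33,-1.88,-1.14,0,ET
28,54,M,5,1,2.52,2.52,-1.84,-1.27,0,ET
29,75,M,28,5,2.42,1.94,-1.32,-1.88,0,PD
30,70,M,9,1,2.15,1.96,-1.99,-1.97,0,ET
31,67,F,9,1,2.91,2.73,-0.73,-0.46,0,ET
32,71,F,7,1,2.88,2.8,-0.67,-0.2,0,ET
33,69,F,32,7,1.96,1.3,-2.39,-3.33,100,PD
34,67,M,13,5,1.44,1.06,-3.42,-3.82,0,PD
35,70,F,9,1,2.16,1.95,-1.96,-1.99,0,ET
36,55,M,4,0,2.44,2.15,-1.97,-1.99,0,ET
37,68,F,4,0,2.23,1.88,-1.88,-2.19,0,ET
38,72,M,6,0,2.41,2.25,-1.57,-1.3,0,ET
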
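subject_id,ve_peak,age,weight,height,vo2peak,hr_max,vo2vent_measured
1,71.66,28,50.80,168.70,2.1681,191,0.42
2,149.29,27,71.30,188.70,4.1311,176,0.70
3,76.35,21,66.50,167.60,3.6010,185,0.50
4,87.85,23,38.10,171.10,2.3931,185,0.46
5,106.09,37,65.00,180.90,4.3459,172,0.67
6,107.18,33,72.50,171.70,3.7722,179,0.46
7,166.25,21,94.60,188.30,5.0810,186,0.73
8,105.23,22,60.40,171.20,3.2254,188,0.59
9,90.53,33,59.10,167.80,3.9077,197,0.50
10,122.81,30,78.00,185.00,4.6613,185,0.76
11,115.19,39,81.60,180.10,4.4480,171,0.56
12,142.14,43,87.00,179.00,3.4269,158,0.74
13,150.77,30,69.50,179.40,4.4765,174,0.70
14,150.85,32,87.70,181.30,6.5328,184,1.05
15,57.71,28,50.80,168.70,2.1681,191,0.42
16,139.88,26,83.60,184.70,4.5972,184,0.92
17,117.56,24,84.00,184.40,4.5368,160,0.53
18,143.44,26,93.20,195.70,5.5892,180,0.85
19,150.85,30,92.80,185.40,4.8572,175,1.05
20,125.98,25,76.80,184.40,4.8084,165,1.11
21,159.89,28,70.00,180.00,5.03,170,1.06
22,173.99,36,67.30,177.50,4.47,180,1.30
23,141.71,20,59.00,165.00,3.98,174,1.05
24,153.98,32,72.00,176.00,4.72,182,1.17
25,110.82,41,68.00,165.00,2.90,180,0.79
26,150.29,29,84.40,170.00,3.89,190,1.08
27,82.18,22,50.00,159.00,2.22,182,0.59
28,179.26,41,90.00,179.00,3.46,177,1.28
29,139.61,25,74.00,165.00,4.39,171,0.99
30,105.84,27,59.10,175.00,3.45,184,0.68
31,168.44,29,77.00,183.00,4.52,179,1.31
32,153.06,44,69.00,176.00,3.40,172,1.06
33,172.22,29,77.00,185.00,4.91,177,1.28
34,85.17,22,52.00,152.00,2.06,180,0.71
35,90.24,22,56.00,160.00,3.09,188,0.65
36,162.61,26,83.00,173.00,4.11,186,1.15
37,129.74,29,76.60,177.00,4.88,192,1.13
38,90.64,25,47.00,152.00,1.82,189,0.55
39,119.70,24,80.00,185.00,3.92,171,0.81
40,90.77,22,69.00,170.00,3.95,183,0.77
41,189.87,23,74.00,186.00,5.46,186,1.57
42,155.00,40,80.00,180.00,5.32,191,1.25
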
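subject_id,sex,vo2max,vo2vent,percent_of_vo2max
1,M,5.9,0.91,15.42
2,M,5.69,0.75,13.18
3,M,5.09,0.93,18.27
4,M,5.41,0.77,14.23
5,F,3.8,0.61,16.05
6,M,5.91,1.1,18.61
7,M,4.97,0.88,17.71
8,F,2.24,0.53,23.66
9,M,4.94,1.1,22.27
10,M,4.24,0.59,13.92
11,M,4.42,0.92,20.81
12,M,4.87,0.95,19.51
13,M,4.33,0.8,18.48
14,M,4.85,0.58,11.96
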
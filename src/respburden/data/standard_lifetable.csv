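age_start,life_expectancy
0,86.6
5,81.8
10,76.8
15,71.8
20,66.9
25,62.0
30,57.0
35,52.1
40,47.2
45,42.4
50,37.6
55,32.9
60,28.3
65,23.8
70,19.5
75,15.4
80,11.9
85,8.9
90,6.6
95,4.9
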
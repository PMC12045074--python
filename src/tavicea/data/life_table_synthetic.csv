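age,sex,annual_mortality_prob
70,male,0.018906
71,male,0.020811
72,male,0.022907
73,male,0.02521
74,male,0.027742
75,male,0.030524
76,male,0.033581
77,male,0.036938
78,male,0.040623
79,male,0.044667
80,male,0.049103
81,male,0.053967
82,male,0.059298
83,male,0.065137
84,male,0.071529
85,male,0.078522
86,male,0.086166
87,male,0.094515
88,male,0.103626
89,male,0.113559
90,male,0.124376
91,male,0.136143
92,male,0.148925
93,male,0.16279
94,male,0.177806
95,male,0.19404
96,male,0.211557
97,male,0.230417
98,male,0.250676
99,male,0.272382
100,male,0.295572
101,male,0.320269
102,male,0.34648
103,male,0.374192
104,male,0.403368
105,male,0.433943
106,male,0.465822
107,male,0.498872
108,male,0.532927
109,male,0.567777
110,male,1.0
70,female,0.01233
71,female,0.013577
72,female,0.01495
73,female,0.01646
74,female,0.018121
75,female,0.019948
76,female,0.021958
77,female,0.024167
78,female,0.026596
79,female,0.029265
80,female,0.032197
81,female,0.035418
82,female,0.038955
83,female,0.042837
84,female,0.047096
85,female,0.051767
86,female,0.056887
87,female,0.062496
88,female,0.068639
89,female,0.075361
90,female,0.082711
91,female,0.090742
92,female,0.09951
93,female,0.109073
94,female,0.119492
95,female,0.130832
96,female,0.143158
97,female,0.156537
98,female,0.171037
99,female,0.186726
100,female,0.203669
101,female,0.221929
102,female,0.241565
103,female,0.262628
104,female,0.285159
105,female,0.309189
106,female,0.334733
107,female,0.361786
108,female,0.390322
109,female,0.42029
110,female,1.0
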
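age_low_years,age_high_years,mean_weight_kg
6,7,22.5
7,8,27.4
8,9,31.3
9,10,36.2
10,11,39.5
11,12,44.6
12,13,50.3
13,14,56.9
14,15,61.5
15,16,65.9
16,17,68.0
17,18,66.6
18,,80
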
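age_group,sex,population_thousands,cases
0-19,M,3700,79756
20-39,M,5513,28985
40-64,M,7522,45394
65-79,M,3563,30560
80+,M,970,26580
0-19,F,3512,34019
20-39,F,5137,11329
40-64,F,7195,46180
65-79,F,3961,84423
80+,F,1714,120825
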
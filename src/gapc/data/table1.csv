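age_group,female_cases,female_population,male_cases,male_population
[25-30),29,39112750,30,40674966
[30-35),78,40479316,127,42050505
[35-40),208,39037967,343,40159381
[40-45),456,36471240,950,36921758
[45-50),886,33664579,1819,33514408
[50-55),1477,30392137,3165,29678151
[55-60),2339,28256099,4751,26894691
[60-65),3631,26988257,6563,24844905
[65-70),5254,25364551,8319,22216742
[70-75),7052,22899701,9015,18417269
[75-80),8999,19621682,8729,13916416
[80-85),8764,14420414,6328,8697951
[85-+),9173,12417814,4513,5711393
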
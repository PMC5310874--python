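age_group,weight
[25-30),6000
[30-35),6500
[35-40),7000
[40-45),7000
[45-50),7000
[50-55),7000
[55-60),6500
[60-65),6000
[65-70),5500
[70-75),5000
[75-80),4000
[80-85),2500
[85-+),2500
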
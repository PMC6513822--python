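zone_code,p10,p20,p30,p40,p50,p60,p70,p80,employees,self_employed,other
E08000002,144.0,219.8,293.0,358.7,408.3,480.5,584.7,669.9,75296,10053,58909
E08000003,90.0,161.1,237.4,288.5,342.9,402.7,473.2,556.0,168744,19342,176463
E08000004,116.2,220.7,261.4,304.6,359.9,428.5,483.5,571.6,81969,10434,77856
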
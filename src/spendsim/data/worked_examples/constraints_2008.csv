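zone_code,variable,category,count
E08000002,student,student,5745
E08000002,student,not_student,138513
E08000002,unemployment,unemployed,3503
E08000002,unemployment,not_unemployed,140755
E08000002,ethnicity,white,134004
E08000002,ethnicity,mixed,804
E08000002,ethnicity,black,1106
E08000002,ethnicity,other,8344
E08000003,student,student,22054
E08000003,student,not_student,342495
E08000003,unemployment,unemployed,20375
E08000003,unemployment,not_unemployed,344174
E08000003,ethnicity,white,281654
E08000003,ethnicity,mixed,5336
E08000003,ethnicity,black,22105
E08000003,ethnicity,other,55454
E08000004,student,student,8115
E08000004,student,not_student,162144
E08000004,unemployment,unemployed,8416
E08000004,unemployment,not_unemployed,161843
E08000004,ethnicity,white,139659
E08000004,ethnicity,mixed,1405
E08000004,ethnicity,black,8032
E08000004,ethnicity,other,8392
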
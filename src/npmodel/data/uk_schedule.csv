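label,age_start,age_end,generation,turnover_per_year,observed_5yr_pct
0 ~ 5,0,5,45,4.2E+13,0.1028
~ 10,5,10,46,4.2E+13,0.0553
~ 15,10,15,47,4.2E+13,0.0633
~ 20,15,20,47.5,4.2E+13,0.1023
~ 25,20,25,48,4.2E+13,0.1643
~ 30,25,30,48.5,4.2E+13,0.3003
~ 35,30,35,49,4.2E+13,0.4533
~ 40,35,40,49.5,3.15E+13,0.6380
~ 45,40,45,50,2.36E+13,0.9550
~ 50,45,50,50.5,1.77E+13,1.5588
~ 55,50,55,51,1.33E+13,2.3953
~ 60,55,60,51.5,9.97E+12,3.5565
~ 65,60,65,52,7.48E+12,5.3138
~ 70,65,70,52.5,5.61E+12,7.5760
~ 75,70,75,53,4.2E+12,9.5098
~ 80,75,80,53.5,2.73E+12,11.8208
~ 85,80,85,54,1.78E+12,13.0510
~ 90,85,90,54.5,1.07E+12,14.2038
~ 95,90,95,55,5.33E+11,13.3100
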
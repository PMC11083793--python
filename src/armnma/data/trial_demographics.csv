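study,year,country,arm_label_reported,group,n,age_mean,age_sd,male,female,bmi_mean,bmi_sd,staging_system,stage_i,stage_ii,stage_iii,stage_iv,hist_intestinal_differentiated,hist_diffuse_undifferentiated,neoadjuvant,adjuvant
Huscher2005,2005,Italy,OpDG,OpDG,29,63.6,13.2,21,8,NA,NA,AJCC 1997,9,5,11,4,18,11,NA,NA
Huscher2005,2005,Italy,LapDG,LapDG,30,63.2,12.5,18,12,NA,NA,AJCC 1997,13,4,8,5,16,14,NA,NA
Hu2012,2012,China,OpDG,OpDG,20,64.5,6.5,12,8,23.4,2.6,NR,7,11,2,NA,NA,NA,0,NA
Hu2012,2012,China,LapDG,LapAsDG,22,62.5,6.75,10,12,22.9,2.2,NR,11,10,1,NA,NA,NA,0,NA
Hu2016,2016,China,OpDG,OpDG,520,55.8,11.1,346,174,22.7,3.2,AJCC 7th,152,138,221,8,365,155,0,NA
Hu2016,2016,China,LapDG,LapAsDG,519,56.5,10.4,380,139,22.7,3.3,AJCC 7th,151,77,219,11,361,158,0,NA
Shi2018,2018,China,OpDG,OpDG,102,NA,NA,NA,NA,NA,NA,AJCC 6th,10,NA,NA,NA,38,122,0,NA
Shi2018,2018,China,LapDG,LapAsDG,94,NA,NA,NA,NA,NA,NA,AJCC 6th,16,NA,NA,NA,45,117,0,NA
Park2018,2018,Korea,OpDG,OpDG,96,60.1,8.2,65,31,23.3,3.1,AJCC 7th,36,33,23,4,96,0,0,NA
Park2018,2018,Korea,LapDG,LapDG,100,58.6,8.9,69,31,23.7,3.0,AJCC 7th,42,29,28,1,100,0,0,NA
Wang2019,2019,China,OpDG,OpDG,220,60.6,10.2,133,87,23.5,3.3,AJCC 7th,68,63,83,6,59,161,0,NA
Wang2019,2019,China,LapAsDG,LapAsDG,222,59.4,12.4,144,78,23.1,3.1,AJCC 7th,75,63,80,4,47,175,0,NA
Li2019,2019,China,OpDG,OpDG,50,61,2.25,34,16,22.6,0.9,AJCC 7th,16,19,12,0,10,40,50,50
Li2019,2019,China,LapAsDG,LapAsDG,45,59,3.25,32,13,23.5,1.0,AJCC 7th,13,18,10,0,10,35,45,45
Lee2019,2019,Korea,OpDG,OpDG,498,59.6,11.5,346,152,23.7,3.3,NR,167,170,154,7,498,0,0,NA
Lee2019,2019,Korea,LapDG,LapDG,513,59.8,11.1,370,143,23.5,2.9,NR,181,151,172,9,513,0,0,NA
Lu2021,2021,China,LapDG,LapDG,142,59.3,11.3,90,52,22.7,3.3,AJCC 8th,43,36,63,0,56,86,0,19
Lu2021,2021,China,RobDG,RobDG,141,59.4,10.2,94,47,23.2,3.0,AJCC 8th,55,33,53,0,52,89,0,18
Etoh2023,2023,Japan,OpDG,OpDG,233,66,7.8,160,73,22.7,NA,AJCC 7th,95,67,71,0,NA,NA,0,NA
Etoh2023,2023,Japan,LapDG,LapDG,227,64,6.6,156,71,22.3,NA,AJCC 7th,91,64,72,0,NA,NA,0,NA
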
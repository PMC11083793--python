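study,treatment,events,total
Huscher2005,OpDG,0,29
Huscher2005,LapDG,0,30
Hu2012,OpDG,0,20
Hu2012,LapAsDG,0,22
Hu2016,OpDG,0,520
Hu2016,LapAsDG,0,519
Shi2018,OpDG,0,102
Shi2018,LapAsDG,0,94
Park2018,OpDG,0,96
Park2018,LapDG,0,100
Wang2019,OpDG,0,220
Wang2019,LapAsDG,0,222
Li2019,OpDG,0,50
Li2019,LapAsDG,0,45
Lee2019,OpDG,0,498
Lee2019,LapDG,0,513
Lu2021,LapDG,0,142
Lu2021,RobDG,0,141
Etoh2023,OpDG,0,233
Etoh2023,LapDG,0,227
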
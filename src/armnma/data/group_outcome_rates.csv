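outcome,kind,unit,group,mean,low,high
anastomotic_leak,binary,percent,OpDG,1.2,0.0,2.2
anastomotic_leak,binary,percent,LapAsDG,1.5,0.0,2.2
anastomotic_leak,binary,percent,LapDG,1.2,0.0,1.7
anastomotic_leak,binary,percent,RobDG,0.0,0.0,0.0
severe_complications,binary,percent,OpDG,6.4,0.0,17.7
severe_complications,binary,percent,LapAsDG,3.8,2.2,13.3
severe_complications,binary,percent,LapDG,6.4,0.0,11.0
severe_complications,binary,percent,RobDG,1.4,1.4,1.4
overall_complications,binary,percent,OpDG,18.4,10.7,46.0
overall_complications,binary,percent,LapAsDG,15.0,11.1,36.2
overall_complications,binary,percent,LapDG,16.0,11.0,30.2
overall_complications,binary,percent,RobDG,9.0,9.0,9.0
in_hospital_mortality,binary,percent,OpDG,0.3,0.0,6.8
in_hospital_mortality,binary,percent,LapAsDG,0.2,0.0,0.4
in_hospital_mortality,binary,percent,LapDG,0.03,0.0,3.3
in_hospital_mortality,binary,percent,RobDG,0.0,0.0,0.0
surgical_site_infection,binary,percent,OpDG,2.8,0.0,6.8
surgical_site_infection,binary,percent,LapAsDG,1.1,0.0,1.3
surgical_site_infection,binary,percent,LapDG,2.9,0.0,6.6
surgical_site_infection,binary,percent,RobDG,1.0,1.0,1.0
bleeding_transfusion,binary,percent,OpDG,2.0,0.0,6.1
bleeding_transfusion,binary,percent,LapAsDG,1.0,0.0,2.3
bleeding_transfusion,binary,percent,LapDG,1.1,0.0,2.1
bleeding_transfusion,binary,percent,RobDG,1.0,1.0,1.0
pulmonary_complications,binary,percent,OpDG,4.1,0.0,21.0
pulmonary_complications,binary,percent,LapAsDG,5.0,2.1,7.3
pulmonary_complications,binary,percent,LapDG,4.7,2.6,17.2
pulmonary_complications,binary,percent,RobDG,5.9,5.9,5.9
cardiovascular_complications,binary,percent,OpDG,0.0,0.0,3.1
cardiovascular_complications,binary,percent,LapAsDG,1.1,0.0,4.2
cardiovascular_complications,binary,percent,LapDG,0.0,0.0,1.4
cardiovascular_complications,binary,percent,RobDG,1.1,1.1,1.1
reoperation,binary,percent,OpDG,1.8,0.0,3.6
reoperation,binary,percent,LapAsDG,1.8,0.0,2.1
reoperation,binary,percent,LapDG,1.1,0.0,1.7
reoperation,binary,percent,RobDG,0.0,0.0,0.0
positive_resection_margin,binary,percent,OpDG,1.9,0.0,8.2
positive_resection_margin,binary,percent,LapAsDG,0.9,0.0,2.1
positive_resection_margin,binary,percent,LapDG,1.1,0.0,2.1
positive_resection_margin,binary,percent,RobDG,NA,NA,NA
operative_time,continuous,minutes,OpDG,180.8,123.2,209.9
operative_time,continuous,minutes,LapAsDG,231.3,196.0,227.1
operative_time,continuous,minutes,LapDG,240.0,185.0,240.0
operative_time,continuous,minutes,RobDG,201.0,201.0,201.0
blood_loss,continuous,mL,OpDG,165.0,58.7,523.0
blood_loss,continuous,mL,LapAsDG,139.0,95.0,236.0
blood_loss,continuous,mL,LapDG,127.0,84.0,320.0
blood_loss,continuous,mL,RobDG,41.2,41.2,41.2
time_to_flatus,continuous,days,OpDG,3.7,2.2,4.0
time_to_flatus,continuous,days,LapAsDG,3.1,2.5,3.5
time_to_flatus,continuous,days,LapDG,3.2,2.3,3.4
time_to_flatus,continuous,days,RobDG,3.2,3.2,3.2
time_to_oral_intake,continuous,days,OpDG,4.5,2.9,7.8
time_to_oral_intake,continuous,days,LapAsDG,4.6,3.4,6.5
time_to_oral_intake,continuous,days,LapDG,4.4,3.2,6.1
time_to_oral_intake,continuous,days,RobDG,3.5,3.5,3.5
hospital_length_of_stay,continuous,days,OpDG,10.6,8.1,18.8
hospital_length_of_stay,continuous,days,LapAsDG,9.5,8.8,10.7
hospital_length_of_stay,continuous,days,LapDG,9.1,8.4,11.2
hospital_length_of_stay,continuous,days,RobDG,7.9,7.9,7.9
lymph_nodes,continuous,count,OpDG,40.2,31.4,76.5
lymph_nodes,continuous,count,LapAsDG,38.5,30.0,46.6
lymph_nodes,continuous,count,LapDG,37.1,29.1,47.2
lymph_nodes,continuous,count,RobDG,40.9,40.9,40.9
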
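patient_id,practice_id,age_band,sex,ethnicity,region,imd_quintile,rural_urban,dementia,learning_disability,serious_mental_illness,care_home,housebound,registration_start,death_date
p0,gp0000,50-59,female,White,East,3,3,False,False,False,False,False,2010-01-01,
p1,gp0001,50-59,female,White,East,3,3,False,False,False,False,False,2010-01-01,
p2,gp0000,50-59,female,White,East,3,3,False,False,False,False,False,2010-01-01,
p3,gp0001,50-59,female,White,East,3,3,False,False,False,False,False,2010-01-01,
p4,gp0000,50-59,female,White,East,3,3,False,False,False,False,False,2010-01-01,
p5,gp0001,50-59,female,White,East,3,3,False,False,False,False,False,2010-01-01,
p6,gp0000,50-59,female,White,East,3,3,False,False,False,False,False,2010-01-01,
p7,gp0001,50-59,female,White,East,3,3,False,False,False,False,False,2010-01-01,
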
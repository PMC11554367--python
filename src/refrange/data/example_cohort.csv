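subject_id,sex,age,weight_kg,height_m,insulin_uU_mL,glucose_mg_dL,a1c_pct,hdl_mg_dL,tg_mg_dL,med_antidiabetic,med_lipid_lowering,med_antihypertensive,yearly_exam_count
P01,F,35,60.0,1.65,6.2,90,5.4,55,100,False,False,False,1
P02,F,30,67.8,1.65,8.1,99,5.6,50,149,False,False,False,2
P03,M,44,72.0,1.75,5.9,91,5.3,40,130,False,False,False,1
P04,M,27,70.0,1.74,7.4,85,5.1,48,95,False,False,False,1
P05,F,60,58.0,1.60,5.1,87,5.2,61,80,False,False,False,2
F01,M,45,81.0,1.80,6.8,92,5.4,52,110,False,False,False,1
F02,F,28,48.0,1.65,4.9,88,5.3,58,90,False,False,False,1
F03,M,50,75.0,1.78,9.0,100,5.4,47,120,False,False,False,1
F04,F,40,62.0,1.66,7.7,94,5.7,56,105,False,False,False,2
F05,M,33,78.0,1.77,8.3,93,5.5,45,150,False,False,False,1
F06,F,38,65.0,1.68,6.0,88,5.2,49,120,False,False,False,1
F07,F,55,59.0,1.62,5.5,86,5.1,63,99,False,False,True,1
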
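subject_id,age,sex,systolic_bp,diastolic_bp,antihypertensive_use,diabetes,coronary_artery_disease,cerebrovascular_disease,peripheral_artery_disease,heart_failure,valvular_disease,arrhythmia,egfr,ckd_diagnosis,current_smoker,bmi,total_cholesterol,hdl_cholesterol,prior_anthracycline,prior_nonanthracycline_chemo,prior_chest_rt,followup_years,cancer_type,metastatic,received_anthracycline,received_her2,received_vegf_iv,received_myeloma_tx,received_cardiotoxic_rt
S0,79.53622374218955,female,128.2707270725804,78.80061321238098,0,0,1,0,0,0,0,0,74.61933335187929,0,0,25.1940272096026,5.516600782404549,0.8422208780443147,0,1,0,14.753204034412784,gastrointestinal,0,0,0,0,0,0
S1,49.91800287989437,female,138.6500409262263,73.68792060790629,0,0,0,0,0,0,0,0,66.46483647229653,0,0,25.608811687926487,4.926240850012942,1.2082819698703384,0,0,0,13.624642169343554,breast,0,0,0,0,0,0
S2,50.652935612952945,male,132.82342130526584,83.77066866974342,0,0,0,0,0,0,0,0,99.04155365656808,0,0,29.9,5.351141292569057,1.250075422659947,0,0,0,16.23963769272831,breast,0,0,0,0,0,0
S3,50.01291855550717,female,132.7603281590572,76.61182839791904,0,0,0,0,0,0,0,0,79.78497893665164,0,0,28.13846662694985,7.331279438722828,1.8157656329272829,0,0,0,14.95783009045217,other_solid,0,1,0,1,0,0
S4,63.76060919780053,male,142.9519784266863,82.40177600314291,0,0,0,0,0,0,0,0,79.18873670956421,0,0,26.86868161513746,4.50731806783089,1.2073180678308904,0,0,0,15.556700462511083,melanoma,0,1,0,0,0,0
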
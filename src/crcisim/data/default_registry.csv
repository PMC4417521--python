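name,min_age,max_age,sex,risk_predicate,interval_years,uptake,included_in_crci,estimated,exclusion_group
dpt_hib_primary,0,0,any,none,1,0.969,true,false,
pneumococcal_primary,0,0,any,none,1,0.966,true,false,
meningococcal_b,0,0,any,none,1,0.966,true,false,
rotavirus,0,0,any,none,1,0.940,true,true,
pneumococcal_booster,1,1,any,none,1,0.943,true,false,
hib_menc_booster,1,1,any,none,1,0.945,true,false,
mmr_first_dose,1,1,any,none,1,0.935,true,false,
influenza_child,2,15,any,none,1,0.450,true,true,influenza
dpt_polio_preschool,3,3,any,none,1,0.923,true,false,
mmr_second_dose,3,3,any,none,1,0.935,true,false,
hpv,13,14,female,none,1,0.834,true,false,
chlamydia_screen,16,25,any,none,1,0.350,false,true,
cervical_screen,20,64,female,none,3,0.765,true,false,
breast_screen,50,70,female,none,3,0.733,true,false,
bowel_screen,60,70,any,none,2,0.540,true,false,
influenza_65plus,65,105,any,none,1,0.682,true,false,influenza
varicella_zoster_female,65,70,female,none,1,0.600,true,true,
varicella_zoster_male,71,74,male,none,1,0.600,true,true,
influenza_pregnancy,16,44,female,pregnant,1,0.431,true,false,influenza
influenza_at_risk,0,64,any,at_risk_flu,1,0.520,true,false,influenza
retinal_screen_diabetic,13,105,any,diabetic,1,0.810,true,false,
smoking_cessation,16,105,any,smoker,1,0.090,true,false,
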
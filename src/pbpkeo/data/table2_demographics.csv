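study,race_population,dose_mg,n_subjects,age_range_yr,proportion_female_pct,bmi_or_weight,albumin_g_dL,purpose
Planchard,Japanese NSCLC,20;40;80;160;240,28,55-70,75,BMI mean 26.6,,develop model with plasma PK
Zhao_40,Chinese NSCLC,40,15,33-73,47,BMI 16-31,,validate plasma PK
Zhao_80,Chinese NSCLC,80,16,35-76,69,BMI 18-32,,validate plasma PK
Harvey,White NSCLC,80,49,44-83,71,BMI mean 23.0,,validate plasma PK
Grande,White NSCLC,80,10,56-73,60,,2.8-3.5,validate plasma PK
Goldstein,Brain metastatic NSCLC,80,11,31-74,46,,,confirm intracranial PK
Yamaguchi,Japanese brain metastatic NSCLC,80,40,41-84,70,,,validate intracranial PK
Leeuw,Brain metastatic NSCLC,80,4,61-70,75,,,validate intracranial PK
Fukuhara,Japanese metastatic and non-metastatic NSCLC,80,41,43-81,80,,,validate intracranial PK
Ekman,Brain metastatic NSCLC,80,4,50-80,50,,,validate intracranial PK
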
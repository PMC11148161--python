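perpetrator,scenario,predicted_auc_ratio,predicted_cmax_ratio,observed_auc_ratio,observed_cmax_ratio
ITR,single_dose_study,1.60,1.06,1.26,0.83
RIF,repeated_dose_study,0.16,0.40,0.20,0.26
ITR,day14,2.21,1.60,,
FLUC,day14,1.75,1.32,,
FLUV,day14,1.41,1.20,,
RIF,day14,0.15,0.38,,
EFA,day14,0.28,0.50,,
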
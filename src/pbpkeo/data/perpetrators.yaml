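# Reduced exposure models and enzyme-interaction terms for the five CYP
# perpetrators. The source publication took these from its supplementary
# tables, which are not reproduced in the main text; every value below is a
# literature-sourced substitute (flagged per entry) chosen once from the
# ranges commonly used in PBPK DDI modeling. Exposure model: one-compartment,
# first-order absorption, linear clearance; interaction terms act on the
# victim's per-enzyme intrinsic clearances (competitive inhibition and/or
# turnover-based Emax induction on unbound perpetrator concentration).
enzyme_turnover_halflife_h: 36.0   # CYP3A4 turnover governing induction onset

itraconazole:
  regimen: {dose_mg: 200.0, interval_h: 12.0}
  molecular_weight: 705.6
  oral_clearance_L_h: 18.0        # CL/F; literature range ~10-25 L/h
  volume_L: 700.0                 # V/F
  ka_per_h: 0.5
  fu: 0.036                       # strongly protein bound
  css_avg_unbound_uM_reference: 0.047   # closed-form check value for the fixture
  inhibition:
    CYP3A4: {ki_u_uM: 0.0013}     # potent competitive CYP3A inhibition
    CYP3A5: {ki_u_uM: 0.0013}

fluconazole:
  regimen: {dose_mg: 150.0, interval_h: 24.0}
  molecular_weight: 306.3
  oral_clearance_L_h: 0.77        # renally cleared, t1/2 ~30 h
  volume_L: 45.0
  ka_per_h: 1.0
  fu: 0.89
  css_avg_unbound_uM_reference: 23.6
  inhibition:
    CYP3A4: {ki_u_uM: 25.0}       # moderate CYP3A inhibition
    CYP3A5: {ki_u_uM: 25.0}
    CYP2C9: {ki_u_uM: 8.0}

fluvoxamine:
  regimen: {dose_mg: 50.0, interval_h: 24.0}
  molecular_weight: 318.3
  oral_clearance_L_h: 60.0
  volume_L: 1200.0
  ka_per_h: 0.8
  fu: 0.23
  css_avg_unbound_uM_reference: 0.025
  inhibition:
    CYP1A2: {ki_u_uM: 0.035}      # potent CYP1A2 inhibition
    CYP2C9: {ki_u_uM: 8.0}

rifampicin:
  regimen: {dose_mg: 600.0, interval_h: 24.0}
  molecular_weight: 822.9
  oral_clearance_L_h: 14.0
  volume_L: 70.0
  ka_per_h: 1.0
  fu: 0.20
  css_avg_unbound_uM_reference: 0.434
  induction:
    CYP3A4: {emax_fold: 12.0, ec50_u_uM: 0.10}
    CYP2C9: {emax_fold: 2.5,  ec50_u_uM: 0.10}
    CYP1A2: {emax_fold: 1.5,  ec50_u_uM: 0.10}

efavirenz:
  regimen: {dose_mg: 600.0, interval_h: 24.0}
  molecular_weight: 315.7
  oral_clearance_L_h: 9.0
  volume_L: 250.0
  ka_per_h: 0.6
  fu: 0.010
  css_avg_unbound_uM_reference: 0.088
  induction:
    CYP3A4: {emax_fold: 6.0, ec50_u_uM: 0.017}
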
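# Drug-specific, binding-kinetic and disease-physiology input parameters for
# the osimertinib PBPK-EO model. One entry per published table row; units are
# explicit strings so the loader can assert them.
compound:
  molecular_weight: {value: 499.6, unit: g/mol}        # physicochemical: MW
  pka_base_strong: {value: 9.5, unit: unitless}        # base pKa (dominant site)
  pka_base_weak: {value: 4.4, unit: unitless}          # base pKa (weak site, stored only)
  log_p: {value: 5.45, unit: unitless}                 # lipophilicity
  solubility_water: {value: 3.1, unit: mg/mL}          # aqueous solubility
  fu_plasma: {value: 0.011, unit: fraction}            # fraction unbound in plasma (albumin)
  blood_plasma_ratio: {value: 1.0, unit: unitless}     # Rbp

absorption:
  gastric_emptying_time: {value: 120.0, unit: min}     # GET
  effective_permeability: {value: 0.187, unit: 1e-4 cm/s}  # Peff
  weibull_t50: {value: 15.0, unit: min}                # dissolution time of 50%
  weibull_shape: {value: 0.92, unit: unitless}

distribution:
  kp_scale: {value: 1.5, unit: unitless}               # organ-to-plasma Kp scale
  k_brt_plasma: {value: 2.89, unit: unitless}          # total brain-to-plasma ratio
  partition_method: rodgers_rowland

metabolism:
  cyp_clint:                                           # unbound intrinsic clearance
    CYP1A2: {value: 0.52, unit: uL/min/pmol}
    CYP2A6: {value: 0.37, unit: uL/min/pmol}
    CYP2C9: {value: 0.48, unit: uL/min/pmol}
    CYP2E1: {value: 0.11, unit: uL/min/pmol}
    CYP3A4: {value: 0.73, unit: uL/min/pmol}
    CYP3A5: {value: 0.21, unit: uL/min/pmol}
  renal_clearance_rule: gfr_times_fup                  # CL_R = GFR x fup
  gfr: {value: 120.0, unit: mL/min}                    # standard adult GFR (fixture)

brain_transport:
  abcb1_clint: {value: 73.4, unit: uL/min/million-cells}
  bcrp_clint: {value: 15.9, unit: uL/min/million-cells}
  abcb1_conc: {value: 1.3, unit: uM}                   # relative-activity anchor
  bcrp_conc: {value: 2.4, unit: uM}

eo:
  kon:                                                 # association rate constants
    wild_type: {value: 0.028, unit: uM^-1 per-time}
    t790m_l858r: {value: 1.40, unit: uM^-1 per-time}
    l858r: {value: 0.57, unit: uM^-1 per-time}
    c797s: {value: 0.0026, unit: uM^-1 per-time}
  kon_time_base: per_hour        # locked by the mode-selection experiment (see calibration)
  koff: {value: 0.001, unit: 1/h}
  egfr_t0: {value: 0.299, unit: uM}
  egfr_halflife: {value: 27.5, unit: h}                # kdeg = ln2/27.5 = 0.025 1/h

interactions:                                          # osimertinib as perpetrator
  ki_cyp3a: {value: 2.55, unit: uM}
  ki_abcb1: {value: 3.8, unit: uM}
  ki_bcrp: {value: 2.0, unit: uM}
  ec50_cyp3a4: {value: 0.12, unit: uM}
  emax_cyp3a4: {value: 10.8, unit: fold}

physiology_disease:
  hematocrit: {value: 0.33, unit: fraction}
  albumin_patient: {value: 0.31, unit: g/dL}           # stored as printed; used as ratio
  albumin_healthy_reference: {value: 0.45, unit: g/dL}

transport_assay:                                       # bidirectional transwell inputs
  abcb1:
    papp_ab: {value: 1.36, unit: 1e-6 cm/s}
    net_efflux_ratio: {value: 13.4, unit: unitless}
  bcrp:
    papp_ab: {value: 0.83, unit: 1e-6 cm/s}
    net_efflux_ratio: {value: 5.4, unit: unitless}
  filter_surface_area: {value: 1.12, unit: cm^2}       # 12-well transwell insert
  assay_ph: {value: 7.4, unit: unitless}
  # Cell count per insert is not printed; back-calculated so the ABCB1 assay
  # reproduces CLint,u = 73.4 uL/min/million-cells (recorded, not asserted as
  # the authors' value). The same count reproduces the BCRP value 15.9 to
  # three figures, an internal consistency check.
  cell_count_backcalculated: {value: 3.9217, unit: million-cells}
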
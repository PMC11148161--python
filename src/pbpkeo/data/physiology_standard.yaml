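# Standard-human physiology fixture (reference adult, ~70 kg). Organ volumes
# and blood flows follow ICRP-style reference values; hepatic CYP abundances
# are typical liver-microsomal values (pmol/mg microsomal protein) scaled by
# MPPGL. These are artifact plumbing: absolute physiology is not printed in
# the source table, and the residual error is absorbed by the single hepatic
# CLint calibration factor.
body_weight: {value: 70.0, unit: kg}
hematocrit: {value: 0.33, unit: fraction}          # patient value (overrides 0.45 healthy)

# Volumes in L; blood flows in L/h. Flows sum to cardiac output at the lung.
organs:
  lung:    {volume: 0.50,  flow: 390.0}
  liver:   {volume: 1.80,  flow: 25.0}    # hepatic-artery flow only; portal adds gut+spleen
  gut:     {volume: 1.10,  flow: 55.0}
  spleen:  {volume: 0.15,  flow: 5.0}
  kidney:  {volume: 0.31,  flow: 74.0}
  brain:   {volume: 1.45,  flow: 46.0}
  muscle:  {volume: 29.0,  flow: 45.0}
  adipose: {volume: 13.0,  flow: 19.0}
  skin:    {volume: 3.30,  flow: 19.0}
  heart:   {volume: 0.33,  flow: 16.0}
  bone:    {volume: 10.0,  flow: 12.0}
  rest:    {volume: 3.90,  flow: 74.0}
blood:
  venous_volume: {value: 3.40, unit: L}
  arterial_volume: {value: 1.70, unit: L}

brain_subcompartments:            # fractions of total brain volume
  vascular_blood_fraction: 0.045  # split into plasma/blood-cells by hematocrit
  interstitial_fraction: 0.18
  # intracellular = remainder

liver_enzymes:
  mppgl: {value: 40.0, unit: mg microsomal protein / g liver}
  liver_weight: {value: 1800.0, unit: g}
  abundance_pmol_per_mg:          # typical microsomal abundances
    CYP1A2: 52.0
    CYP2A6: 42.0
    CYP2C9: 73.0
    CYP2E1: 61.0
    CYP3A4: 137.0
    CYP3A5: 17.0
intestinal_cyp3a4_total_pmol: 70000.0   # whole small-intestine CYP3A4

brain_cell_count: {value: 1.0e5, unit: million-cells}  # scales transporter CLint to whole brain

absorption_geometry:
  # First-order absorption rate from lumen: ka = Peff * (2/r) * SEF
  intestinal_radius_cm: 1.75
  surface_amplification: 5.0      # plicae/villi amplification at segment scale

# Tissue composition for the Rodgers-Rowland partition equations
# (moderate-to-strong base branch). f_ew/f_iw: extracellular/intracellular
# water fractions; ap: acidic phospholipids (mg/g); f_nl/f_np: neutral
# lipid / neutral phospholipid fractions. Standard reference composition.
tissue_composition:
  adipose: {f_ew: 0.135, f_iw: 0.017, ap: 0.40, f_nl: 0.790,  f_np: 0.0020}
  bone:    {f_ew: 0.100, f_iw: 0.346, ap: 0.67, f_nl: 0.074,  f_np: 0.0011}
  brain:   {f_ew: 0.162, f_iw: 0.620, ap: 0.40, f_nl: 0.051,  f_np: 0.0565}
  gut:     {f_ew: 0.282, f_iw: 0.475, ap: 2.41, f_nl: 0.0487, f_np: 0.0163}
  heart:   {f_ew: 0.320, f_iw: 0.456, ap: 2.25, f_nl: 0.0115, f_np: 0.0166}
  kidney:  {f_ew: 0.273, f_iw: 0.483, ap: 5.03, f_nl: 0.0207, f_np: 0.0162}
  liver:   {f_ew: 0.161, f_iw: 0.573, ap: 4.56, f_nl: 0.0348, f_np: 0.0252}
  lung:    {f_ew: 0.336, f_iw: 0.446, ap: 3.91, f_nl: 0.0030, f_np: 0.0090}
  muscle:  {f_ew: 0.118, f_iw: 0.630, ap: 1.53, f_nl: 0.0100, f_np: 0.0072}
  skin:    {f_ew: 0.382, f_iw: 0.291, ap: 1.32, f_nl: 0.0284, f_np: 0.0111}
  spleen:  {f_ew: 0.207, f_iw: 0.579, ap: 3.18, f_nl: 0.0201, f_np: 0.0198}
  rest:    {f_ew: 0.250, f_iw: 0.480, ap: 2.00, f_nl: 0.0300, f_np: 0.0150}
blood_cells_composition: {f_iw: 0.603, ap: 0.50, f_nl: 0.0017, f_np: 0.0029, ph: 7.22}
plasma_water_fraction: 0.945
intracellular_ph: 7.0
plasma_ph: 7.4
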
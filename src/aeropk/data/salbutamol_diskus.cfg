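# Default parameter set for inhaled salbutamol sulphate in a healthy adult
# (30 y male, 77 kg, BMI 24.9).  YAML key/value format; units in key names or
# comments.  Regional lining volumes, effective absorptive surface areas and
# mucociliary transit times are model calibration constants (tuned once to the
# published single-dose plasma/urine observations for a 600 ug Diskus dose and
# shipped as defaults).

drug:
  name: salbutamol sulphate
  MW_g_mol: 239.32
  logP: 0.74
  pKa: [10.61, 9.35]          # diprotic base convention
  ref_solubility_mg_mL: 270.00   # pH 7.4
  lung_solubility_mg_mL: 384.70  # simulated lung fluid
  Papp_bronchiolar_cm_s: 8.53e-7 # Calu-3
  Papp_alveolar_cm_s: 1.59e-5    # A549
  density_g_mL: 1.33
  B2P: 0.96
  Fup: 0.92
  diffusion_coeff_cm2_s: 0.80e-5

lung_disposition:
  fu_alveolar_cells: 0.15
  fu_ET_cells: 0.20
  fu_TB_cells: 1.00
  swallowed_frac_ET: 0.65
  expectorated_frac_ET: 0.30
  first_pass_extraction: 1.00
  # regional lining-fluid volumes (mL) and effective absorptive areas (cm^2):
  # calibration constants (effective areas are far below anatomical areas,
  # absorbing the unmodelled epithelial diffusion resistance)
  V_ET_mL: 0.4
  SA_ET_cm2: 600.0
  V_TB_mL: 10.0
  SA_TB_cm2: 2000.0
  V_AL_mL: 15.0
  SA_AL_cm2: 14000.0
  # mucociliary transit times (h): TB escalator to the throat, throat to gut
  mcc_transit_TB_h: 6.0
  mcc_transit_ET_h: 2.0

systemic:
  body_weight_kg: 77.0
  age_y: 30
  sex: male
  BMI_kg_m2: 24.9
  CL_renal_mL_min_kg: 4.2
  CL_hepatic_mL_min_kg: 5.44
  plasma_volume_L: 3.78
  venous_plasma_L: 2.27
  arterial_plasma_L: 1.51
  hematocrit: 0.45
  # perfusion-limited tissues: volume (L) and plasma flow (L/h); plasma
  # cardiac output is the flow sum (185 L/h)
  tissues:
    adipose:  {volume_L: 14.50, flow_L_h:  9.5}
    bone:     {volume_L:  7.60, flow_L_h:  9.0}
    brain:    {volume_L:  1.45, flow_L_h: 22.0}
    gut:      {volume_L:  1.25, flow_L_h: 29.5}
    heart:    {volume_L:  0.36, flow_L_h:  7.5}
    kidney:   {volume_L:  0.34, flow_L_h: 35.0}
    liver:    {volume_L:  1.75, flow_L_h: 12.0}
    lung:     {volume_L:  0.55, flow_L_h: 185.0}
    muscle:   {volume_L: 30.00, flow_L_h: 31.5}
    skin:     {volume_L:  2.95, flow_L_h: 10.5}
    spleen:   {volume_L:  0.20, flow_L_h:  3.5}
    rest:     {volume_L:  3.50, flow_L_h: 15.0}
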
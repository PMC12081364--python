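# Final-model defaults: fixed effects, inter-individual variability,
# residual error, and the reference medians used for covariate
# standardization.  Continuous covariates enter as powers of their
# median-normalized value; the bleomycin flag enters as exp(coef * flag).
fixed_effects:
  theta_cl: 12.88        # L/h, typical clearance at reference covariates
  theta_vc: 72.04        # L, typical central volume at reference body weight
  beta_egfr_cl: 0.23
  beta_bw_cl: 0.39
  beta_tbil_cl: -0.05
  beta_alb_cl: -0.18
  beta_blm_cl: 0.08      # log-scale shift when bleomycin is co-administered
  beta_bw_vc: 0.31
  q_fixed: 1.08          # L/h, inter-compartmental clearance (fixed)
  vp_fixed: 94.94        # L, peripheral volume (fixed)
iiv:
  omega_cl: 0.30         # log-scale SD of the clearance random effect
  omega_vc: 0.32         # log-scale SD of the central-volume random effect
error:
  kind: proportional
  sigma_prop: 0.37
  sigma_add: 0.0         # μmol/L, used by additive/combined kinds
reference_medians:
  egfr: 102.2            # mL/min/1.73 m^2
  bw: 47.0               # kg
  tbil: 15.3             # μmol/L
  alb: 40.9              # g/L
molar_mass_g_per_mol: 454.44
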
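{
 "comment": "Calibrated default rate constants for the growth-capsulation network (units: s, molecules). k_uxp_prod is the dose knob: 0.003 (switcher) / 0.3 (intermediate) / 3 (ancestor). Certified by sweeps.calibrate_defaults: at k_uxp_prod=0.003 both phenotype states occupy >=10% of the 48-h window with mean dwell >=2 division-equivalents; at k_uxp_prod=3 CAP stays basal (<=1 switch per window).",
 "version": 1,
 "rates": {
  "k_uxp_prod": 0.003,
  "k_cap_feedback": 1e-06,
  "k_pyrg_drain": 0.01,
  "k_seq_on": 0.5,
  "k_seq_off": 0.2,
  "k_act_bind": 0.1,
  "k_act_unbind": 0.5,
  "k_tx_active": 0.6,
  "k_tx_basal": 0.0002,
  "k_tl_ca": 0.05,
  "k_capDNAr_bind": 0.0001,
  "k_capDNAr_unbind": 0.002,
  "k_tx_rep": 0.005,
  "k_tl_rep": 0.0026,
  "k_dim_on": 1.5e-07,
  "k_dim_off": 0.001,
  "k_rep_bind": 0.005,
  "k_rep_unbind": 8e-05,
  "k_deg_mRNAca": 0.06,
  "k_deg_mRNAr": 0.002,
  "k_deg_CA": 0.002,
  "k_deg_R": 0.00025,
  "k_deg_R2": 0.00025
 },
 "init": {
  "uxp_range": [
   20,
   100
  ],
  "activator_range": [
   10,
   10
  ],
  "ca_range": [
   0,
   0
  ],
  "mrna_ca_range": [
   0,
   0
  ],
  "mrna_r_range": [
   0,
   0
  ],
  "r_range": [
   0,
   0
  ],
  "dnaca_copies": 1,
  "dnar_copies": 1
 }
}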
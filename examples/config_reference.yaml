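# Reference configuration: the shipped defaults written out explicitly.
# Any subset may be given; omitted keys take these values.  Units are in the
# key names.  This setup is the one used for the location-dependent STDP
# window runs (proximal 50 um, distal 300 um probes).
cable:
  diameter_um: 1.0        # lambda = sqrt(d*Rm/4Ri) = 500 um
  Cm_uF_cm2: 1.0          # tau = Rm*Cm = 10 ms
  Ri_ohm_cm: 100.0
  Rm_ohm_cm2: 10000.0
  EL_mV: -65.0
  Er_mV: -65.0
  Vmax_mV: 100.0          # peak-voltage normalizer for dimensionless u
stimulus:                 # boundary action-potential clamp at x = 0
  kind: ap_adp
  amplitude_mV: 100.0
  width_ms: 1.2
  adp_amplitude_mV: 16.0  # after-depolarizing tail
  adp_tau_ms: 35.0
  adp_rise_ms: 3.0
  ahp_amplitude_mV: 0.0   # optional fast after-hyperpolarization
  ahp_tau_ms: 8.0
  ahp_rise_ms: 1.0
channels:                 # membrane densities; hotspot counts derived
  Na:   {density_pS_um2: 30.0, gamma_pS: 20.0}
  K_DR: {density_pS_um2: 40.0, gamma_pS: 20.0}
  K_A:  {density_pS_um2: 20.0, gamma_pS: 20.0}
  Ca_T: {density_pS_um2: 3.0, gamma_pS: 10.0}
  Ca_L: {density_pS_um2: 3.0, gamma_pS: 10.0}
hotspots:                 # regular hotspot grid along the cable
  start_um: 25.0
  spacing_um: 50.0
  end_um: 480.0
synapse:
  x_um: 50.0              # default NMDA hotspot position
  nmda:
    gamma_pS: 50.0
    count: 60.0
    E_mV: 0.0
    ECa_mV: 120.0
    tau_rise_ms: 3.0
    tau_decay_ms: 12.0    # fast deactivation component
    tau_slow_ms: 110.0    # slow deactivation component
    fraction_fast: 0.65
    ca_fraction: 0.1
    Mg_mM: 1.0
    pool_capacity: null   # optional receptor-pool saturation
  ca_t_count: 10.0        # co-located calcium clusters at the synapse
  ca_l_count: 10.0
calcium:
  DCa_um2_ms: 0.22
  DB_um2_ms: 0.05
  BT_uM: 100.0
  Kd_uM: 1.0
  Pm_um_ms: 1.0
  Kp_uM: 1.0
  rest_uM: 0.05
  k_on_per_uM_ms: 0.5     # buffer forward rate (finite-difference oracle)
plasticity:               # calcium-control rule
  theta_d: 0.35
  theta_p: 0.55
  beta1: 80.0
  beta2: 80.0
  baseline: 0.25
  eta_p1: 0.1
  eta_p2: 1.0e-05
  eta_p3: 3.0
  eta_p4: 1.0
  lambda_w: 0.0           # weight decay; 0 = per-pairing accumulation
  drive_mode: peak
  pairing_gain_s: 1.0
  ratio_anchor: 0.57
  ratio_anchor_freq_Hz: 2.0
solver:
  dT: 0.01                # dimensionless time step (0.1 ms here)
protocol:
  proximal_um: 50.0
  distal_um: 300.0
  delta_t_min_ms: -100.0
  delta_t_max_ms: 120.0
  delta_t_step_ms: 5.0
  freq_min_Hz: 2.0
  freq_max_Hz: 60.0
  freq_step_Hz: 2.0
  n_pairings: 60
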
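# Default model configuration (all values shown; omit any section or key
# to keep its default).
dt_s: 0.001
output_stride: 1

pool:
  n_units: 120
  a_r: 30.0            # fold range of recruitment thresholds
  rt_max: 0.7          # highest threshold on the excitation scale
  mfr_hz: 8.0
  pfr_min_hz: 46.0
  pfr_max_hz: 56.0
  total_fmax_n: 1433.4
  force_range: 100.0   # fold range of per-unit peak forces
  pulse_width_s: 0.023

activation:
  integrator: exact    # exact | rk45

muscle:
  l_ce_opt_m: 0.077
  phi_opt_rad: 0.17
  l_see_slack_m: 0.223
  fl_width: 0.56
  fl_shape: parabola   # parabola | gaussian
  a_rel: 0.41
  b_rel: 4.5
  f_ecc: 1.5
  see_strain_at_fmax: 0.09
  n_substeps: 8

metabolic:
  phosphate_pool_mm: 42.5
  atp_mm: 8.2
  km_glycolysis_mm: 18.94
  glyc_vmax_fold: 4.0
  glyc_vmax_weighted_mean: 1.5
  theta_gain: 1.4
  pk_ck: 6.75
  pk_pi: 6.75
  beta0_slykes: 20.0
  pi_rest_mm: 4.5
  ph_rest: 7.0
  pi_rate_p1: 0.45     # repo-calibrated; pi rate = p1*(1 - exp(-p3*a))
  pi_rate_p3: 5.0

joint:
  l_ma0_m: 0.027
  l_ma_rel_range: 0.249

controller:
  r_down: 0.7
  k_up: 0.013
  k_down: 0.013
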
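# Default parameters of the cingulo-frontal immune-serotonin circuit model,
# in the printed units of the source tables (time constants in ms, gamma in
# per-ms, Vmax in nM/s, currents in nA, concentrations in nM).  The loader
# converts everything to an internal seconds/Hz/nA/nM frame.
pfc:
  i_thr_e_na: 0.4
  i_thr_i_na: 0.286
  io_na: 0.32
  g_e: 310.0
  g_i: 615.0
  d_e: 0.16
  d_i: 0.087
  j_nmda_na: 0.15
  j: 1.135
  w_5ht_e: 0.48
  w_5ht_i: 0.47
  w_e: 1.0
  w_i: 0.7
  w_plus: 1.4
  r_density: 0.6
  tau_nmda_ms: 100.0
  tau_gaba_ms: 10.0
  gamma_per_ms: 0.000641
  c_in: 0.01          # long-range coupling constant scaling SCC -> PFC input
scc:
  i_thr_e_na: 0.4
  i_thr_i_na: 0.286
  io_na: 0.45
  g_e: 310.0
  g_i: 615.0
  d_e: 0.16
  d_i: 0.087
  j_nmda_na: 0.33
  j: 1.135
  w_5ht_e: 0.19
  w_5ht_i: 0.19
  w_e: 1.0
  w_i: 0.8
  w_plus: 1.4
  r_density: 0.6
  tau_nmda_ms: 100.0
  tau_gaba_ms: 10.0
  gamma_per_ms: 0.000641
  c_in: 0.005         # long-range coupling constant scaling PFC -> SCC input
serotonin:
  alpha: 5.0
  c_br: 15.0
  vmax_nm_per_s: 1300.0
  km_nm: 170.0        # control; SSRI treatment raises to 200
  tau_5ht_ms: 120.0
  j_5ht: 1.0
  beta_per_nm: 0.008
  c1:
    pfc: 5.0
    scc: 4.0
  m: 2.0
  c2: 0.019
inflammation:
  degree: 1.0         # TNFa fold-elevation: 1 / 1.25 / 1.4 / 2.3
  B: 1.0              # anti-inflammatory blocker; 0.55 under treatment
simulation:
  dt_ms: 0.1
  duration_s: 7.0
  transient_s: 1.0
  sigma: 0.01
  n_reps: 100
  base_seed: 2024
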
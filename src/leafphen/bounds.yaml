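# Default calibration bounds per model parameter: [low, high].
# Emergence-window day indices are 1-based from 1 September of the
# preceding year (index 123 = 1 January); senescence start days are
# calendar day of year.  Brackets are physiologically plausible ranges for
# cool-temperate deciduous/conifer canopies; override with a user YAML.
TT:
  t0: [1, 250]
  T_base: [-5.0, 15.0]
  F_star: [10.0, 1000.0]
TTs:
  t0: [1, 250]
  b: [0.05, 5.0]
  c: [-10.0, 20.0]
  F_star: [5.0, 300.0]
PTT:
  t0: [1, 250]
  T_base: [-5.0, 15.0]
  F_star: [10.0, 800.0]
PTTs:
  t0: [1, 250]
  b: [0.05, 5.0]
  c: [-10.0, 20.0]
  F_star: [5.0, 300.0]
M1:
  t0: [1, 250]
  T_base: [-5.0, 15.0]
  k: [0.0, 5.0]
  F_star: [10.0, 1000.0]
AT:
  t0: [1, 200]
  T_c: [-5.0, 10.0]
  a: [0.0, 600.0]
  b: [0.0, 2000.0]
  c: [-1.0, 0.0]
SQ:
  t0_chill: [1, 150]
  T_min: [-15.0, 0.0]
  T_opt: [0.01, 7.99]
  T_max: [8.0, 20.0]
  C_star: [5.0, 150.0]
  T_base: [-5.0, 15.0]
  F_star: [10.0, 800.0]
DP:
  t0_di: [1, 80]
  a_di: [0.05, 2.0]
  b_di: [5.0, 25.0]
  c_di: [8.0, 16.0]
  D_star: [5.0, 100.0]
  a_ch: [0.05, 2.0]
  c_ch: [-5.0, 15.0]
  b_f: [0.05, 2.0]
  c_f: [0.0, 20.0]
  g_L: [0.1, 5.0]
  h_L: [8.0, 20.0]
  F_a: [5.0, 300.0]
  F_b: [0.0, 0.05]
WM:
  L_crit: [8.0, 16.0]
  T_crit: [0.0, 20.0]
  T_frost: [-30.0, 0.0]
DM:
  start: [150, 280]
  T_b: [5.0, 30.0]
  L_b: [8.0, 18.0]
  x: [0.0, 2.0]
  y: [0.0, 2.0]
  Y_star: [1.0, 5000.0]
JM:
  P_crit: [10.0, 16.0]
  T_b: [5.0, 30.0]
  Y_star: [10.0, 1000.0]
DPDI:
  start: [150, 280]
  a: [0.05, 2.0]
  b: [0.0, 25.0]
  c: [8.0, 18.0]
  D_star: [1.0, 100.0]
DMs:
  start: [150, 280]
  T_b: [5.0, 30.0]
  L_b: [8.0, 18.0]
  x: [0.0, 2.0]
  y: [0.0, 2.0]
  Y_star: [1.0, 5000.0]
  alpha: [-0.05, 0.05]
DPDIs:
  start: [150, 280]
  a: [0.05, 2.0]
  b: [0.0, 25.0]
  c: [8.0, 18.0]
  D_star: [1.0, 100.0]
  alpha: [-0.05, 0.05]
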
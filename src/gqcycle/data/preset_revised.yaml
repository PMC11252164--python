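# Experimentally-informed update: k_hyd2 / k_hyd = 20 (inside the accepted
# 1-40 band) and Q209 mutants bind TRIO with a 4-fold elevated association
# rate relative to PLC-beta (effector bias r_trio / r_plc = 4).
k_gef: 1.0
k_hyd: 0.01
k_rgs_on: 10.0
k_rgs_off: 1.0
k_rgs_cat: 2.0
k_on_trio: 10.0
k_off_trio: 1.0
k_on_plc: 10.0
k_off_plc: 0.3
k_hyd2: 0.2
k_gtp_off: 0.001
k_nt_load: 10.0
k_trimer: 10.0
f_act_wt: 0.05
stimulated_f_act: 1.0
R_tot: 0.2
Ga_tot: 1.0
Gbg_tot: 1.0
RGS_tot: 0.2
TRIO_tot: 0.5
PLC_tot: 0.5
variants:
  Q209L: {r_trio: 4.0, r_plc: 1.0, r_hyd: 0.001, r_gap: 0.004, f_act_mut: 1.0}
  Q209P: {r_trio: 4.0, r_plc: 1.0, r_hyd: 0.001, r_gap: 0.004, f_act_mut: 1.0}
  R183C: {r_trio: 1.0, r_plc: 1.0, r_hyd: 0.05, r_gap: 0.2, f_act_mut: 1.0}
  L129Q: {r_trio: 1.0, r_plc: 1.0, r_hyd: 1.0, r_gap: 1.0, f_act_mut: 1.0}
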
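# Default room/ventilation scenarios for the three filling lines.
# Lines L and M share one 2100 m^3 hall with an 18,000 m^3/h (300 m^3/min)
# LEV exhaust; line H sits in a 420 m^3 room with a 2400 m^3/h (40 m^3/min)
# exhaust. q_lev_nf is the FF->NF draw attributed to the LEV. q_gv values
# are nominal open-door natural-ventilation flows (day-specific ACH values
# for the original campaign are not available); near-field volume is a
# 2 m-radius hemisphere rounded to 8 m^3.
L:
  name: L
  v_m3: 2100
  v_nf_m3: 8
  q_gv_m3_per_min: 1050
  q_lev_m3_per_min: 300
  q_lev_nf_m3_per_min: 10
  beta_m3_per_min: 5
  c0_mg_per_m3: 0.0
M:
  name: M
  v_m3: 2100
  v_nf_m3: 8
  q_gv_m3_per_min: 1050
  q_lev_m3_per_min: 300
  q_lev_nf_m3_per_min: 10
  beta_m3_per_min: 5
  c0_mg_per_m3: 0.0
H:
  name: H
  v_m3: 420
  v_nf_m3: 8
  q_gv_m3_per_min: 200
  q_lev_m3_per_min: 40
  q_lev_nf_m3_per_min: 5
  beta_m3_per_min: 5
  c0_mg_per_m3: 0.0
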
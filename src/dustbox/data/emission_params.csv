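filling_line,material,dm_dt_min_kg_per_min,dm_dt_max_kg_per_min,h_factor,lc_bag_retained
L,Clay 1,800,800,1.0,0.3
L,Clay 2,600,600,1.0,0.3
L,Kaolin 1,850,850,1.0,0.3
M,Feldspar 1,530,530,1.0,0.2
M,Quartz 1,550,550,1.0,0.2
H,Feldspar 2,100,250,0.5,0.1
H,Kaolin 2,100,250,0.5,0.1
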
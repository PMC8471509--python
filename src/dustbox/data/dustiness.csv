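material,method,fraction,di_mg_per_kg,sd,en15051_class
Clay 1,CD,inhalable,1733,,low
Clay 1,CD,respirable,6,,low
Clay 1,RD,inhalable,96,,low
Clay 1,RD,respirable,13,,low
Clay 2,CD,inhalable,5170,,medium
Clay 2,CD,respirable,16,,low
Clay 2,RD,inhalable,192,,low
Clay 2,RD,respirable,20,,low
Kaolin 1,CD,inhalable,18886,,high
Kaolin 1,CD,respirable,44,,low
Kaolin 1,RD,inhalable,353,,low
Kaolin 1,RD,respirable,18,,low
Feldspar 1,CD,inhalable,10246,,medium
Feldspar 1,CD,respirable,59,,low
Feldspar 1,RD,inhalable,455,,low
Feldspar 1,RD,respirable,73,,medium
Quartz 1,CD,inhalable,8891,,medium
Quartz 1,CD,respirable,43,,low
Quartz 1,RD,inhalable,480,,low
Quartz 1,RD,respirable,75,,medium
Feldspar 2,CD,inhalable,9651,,medium
Feldspar 2,CD,respirable,77,,medium
Feldspar 2,RD,inhalable,505,,low
Feldspar 2,RD,respirable,34,,low
Kaolin 2,CD,inhalable,12325,,medium
Kaolin 2,CD,respirable,104,,medium
Kaolin 2,RD,inhalable,721,,medium
Kaolin 2,RD,respirable,80,,medium
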
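fraction,model,di_method,filling_line,material,replicate,modelled_mg_m3,measured_mg_m3,measured_no_events_mg_m3,printed_ratio,printed_ratio_no_events
inhalable,one_box,CD,L,Clay 1,R1,92.1,1.85,,50.0,
inhalable,one_box,CD,L,Clay 1,R2,94.5,1.7,,56.0,
inhalable,one_box,CD,L,Clay 1,R3,93.4,1.37,,68.0,
inhalable,one_box,CD,L,Clay 2,R1,263.6,2.0,,132.0,
inhalable,one_box,CD,L,Clay 2,R2,221.2,1.54,,143.0,
inhalable,one_box,CD,L,Kaolin 1,R1,1117.0,2.65,,422.0,
inhalable,one_box,CD,L,Kaolin 1,R2,1266.5,4.71,,269.0,
inhalable,one_box,CD,M,Feldspar 1,R1,198.4,3.42,,58.0,
inhalable,one_box,CD,M,Feldspar 1,R2,285.1,1.41,,201.0,
inhalable,one_box,CD,M,Quartz 1,R1,155.2,1.71,,91.0,
inhalable,one_box,CD,M,Quartz 1,R2,181.8,1.15,,158.0,
inhalable,one_box,CD,H,Feldspar 2,R1,170.9,4.26,0.98,40.0,174.0
inhalable,one_box,CD,H,Feldspar 2,R2,168.7,1.57,1.3,107.0,129.0
inhalable,one_box,CD,H,Kaolin 2,R1,217.9,0.83,,263.0,
inhalable,one_box,CD,H,Kaolin 2,R2,215.3,0.28,,761.0,
inhalable,one_box,RD,L,Clay 1,R1,5.1,1.85,,2.8,
inhalable,one_box,RD,L,Clay 1,R2,5.2,1.7,,3.1,
inhalable,one_box,RD,L,Clay 1,R3,5.2,1.37,,3.8,
inhalable,one_box,RD,L,Clay 2,R1,9.8,2.0,,4.9,
inhalable,one_box,RD,L,Clay 2,R2,8.2,1.54,,5.3,
inhalable,one_box,RD,L,Kaolin 1,R1,20.9,2.65,,7.9,
inhalable,one_box,RD,L,Kaolin 1,R2,23.7,4.71,,5.0,
inhalable,one_box,RD,M,Feldspar 1,R1,8.8,3.42,,2.6,
inhalable,one_box,RD,M,Feldspar 1,R2,12.7,1.41,,9.0,
inhalable,one_box,RD,M,Quartz 1,R1,8.3,1.71,,4.8,
inhalable,one_box,RD,M,Quartz 1,R2,9.7,1.15,,8.4,
inhalable,one_box,RD,H,Feldspar 2,R1,8.9,4.26,0.98,2.1,9.1
inhalable,one_box,RD,H,Feldspar 2,R2,8.8,1.57,1.3,5.6,6.8
inhalable,one_box,RD,H,Kaolin 2,R1,12.8,0.83,,15.0,
inhalable,one_box,RD,H,Kaolin 2,R2,12.6,0.28,,45.0,
inhalable,two_box,CD,L,Clay 1,R1,30.9,1.85,,17.0,
inhalable,two_box,CD,L,Clay 1,R2,31.5,1.7,,19.0,
inhalable,two_box,CD,L,Clay 1,R3,31.3,1.37,,23.0,
inhalable,two_box,CD,L,Clay 2,R1,86.1,2.0,,43.0,
inhalable,two_box,CD,L,Clay 2,R2,72.3,1.54,,47.0,
inhalable,two_box,CD,L,Kaolin 1,R1,362.9,2.65,,137.0,
inhalable,two_box,CD,L,Kaolin 1,R2,410.1,4.71,,87.0,
inhalable,two_box,CD,M,Feldspar 1,R1,65.9,3.42,,19.0,
inhalable,two_box,CD,M,Feldspar 1,R2,94.6,1.41,,67.0,
inhalable,two_box,CD,M,Quartz 1,R1,52.7,1.71,,31.0,
inhalable,two_box,CD,M,Quartz 1,R2,61.8,1.15,,54.0,
inhalable,two_box,CD,H,Feldspar 2,R1,84.8,4.26,0.98,20.0,86.5
inhalable,two_box,CD,H,Feldspar 2,R2,83.2,1.57,1.3,53.0,64.0
inhalable,two_box,CD,H,Kaolin 2,R1,98.3,0.83,,118.0,
inhalable,two_box,CD,H,Kaolin 2,R2,96.8,0.28,,342.0,
inhalable,two_box,RD,L,Clay 1,R1,1.7,1.85,,0.9,
inhalable,two_box,RD,L,Clay 1,R2,1.8,1.7,,1.0,
inhalable,two_box,RD,L,Clay 1,R3,1.7,1.37,,1.3,
inhalable,two_box,RD,L,Clay 2,R1,3.2,2.0,,1.6,
inhalable,two_box,RD,L,Clay 2,R2,2.7,1.54,,1.7,
inhalable,two_box,RD,L,Kaolin 1,R1,6.8,2.65,,2.6,
inhalable,two_box,RD,L,Kaolin 1,R2,7.7,4.71,,1.6,
inhalable,two_box,RD,M,Feldspar 1,R1,2.9,3.42,,0.9,
inhalable,two_box,RD,M,Feldspar 1,R2,4.2,1.41,,3.0,
inhalable,two_box,RD,M,Quartz 1,R1,2.8,1.71,,1.6,
inhalable,two_box,RD,M,Quartz 1,R2,3.3,1.15,,2.9,
inhalable,two_box,RD,H,Feldspar 2,R1,4.4,4.26,0.98,1.0,4.5
inhalable,two_box,RD,H,Feldspar 2,R2,4.4,1.57,1.3,2.8,3.4
inhalable,two_box,RD,H,Kaolin 2,R1,5.8,0.83,,6.9,
inhalable,two_box,RD,H,Kaolin 2,R2,5.7,0.28,,20.0,
respirable,one_box,CD,L,Clay 1,R1,0.32,0.14,,2.2,
respirable,one_box,CD,L,Clay 1,R2,0.33,0.17,,2.0,
respirable,one_box,CD,L,Clay 1,R3,0.32,0.16,,2.0,
respirable,one_box,CD,L,Clay 2,R1,0.82,0.14,,5.9,
respirable,one_box,CD,L,Clay 2,R2,0.68,0.14,,5.0,
respirable,one_box,CD,L,Kaolin 1,R1,2.6,0.24,,11.0,
respirable,one_box,CD,L,Kaolin 1,R2,3.0,0.61,,4.8,
respirable,one_box,CD,M,Feldspar 1,R1,1.1,0.58,,2.0,
respirable,one_box,CD,M,Feldspar 1,R2,1.6,0.12,,14.0,
respirable,one_box,CD,M,Quartz 1,R1,0.76,0.15,,5.0,
respirable,one_box,CD,M,Quartz 1,R2,0.89,0.21,,4.3,
respirable,one_box,CD,H,Feldspar 2,R1,1.4,0.7,0.17,1.9,8.0
respirable,one_box,CD,H,Feldspar 2,R2,1.4,0.29,0.26,4.7,4.7
respirable,one_box,CD,H,Kaolin 2,R1,1.8,0.14,,13.0,
respirable,one_box,CD,H,Kaolin 2,R2,1.8,0.05,,34.0,
respirable,one_box,RD,L,Clay 1,R1,0.69,0.14,,4.8,
respirable,one_box,RD,L,Clay 1,R2,0.71,0.17,,4.3,
respirable,one_box,RD,L,Clay 1,R3,0.7,0.16,,4.3,
respirable,one_box,RD,L,Clay 2,R1,1.0,0.14,,7.3,
respirable,one_box,RD,L,Clay 2,R2,0.86,0.14,,6.4,
respirable,one_box,RD,L,Kaolin 1,R1,1.1,0.24,,4.4,
respirable,one_box,RD,L,Kaolin 1,R2,1.2,0.61,,2.0,
respirable,one_box,RD,M,Feldspar 1,R1,1.4,0.58,,2.4,
respirable,one_box,RD,M,Feldspar 1,R2,2.0,0.12,,17.0,
respirable,one_box,RD,M,Quartz 1,R1,1.3,0.15,,8.5,
respirable,one_box,RD,M,Quartz 1,R2,1.5,0.21,,7.3,
respirable,one_box,RD,H,Feldspar 2,R1,0.6,0.7,0.17,0.9,3.5
respirable,one_box,RD,H,Feldspar 2,R2,0.59,0.29,0.26,2.1,2.0
respirable,one_box,RD,H,Kaolin 2,R1,1.4,0.14,,10.0,
respirable,one_box,RD,H,Kaolin 2,R2,1.4,0.05,,26.0,
respirable,two_box,CD,L,Clay 1,R1,0.11,0.14,,0.8,
respirable,two_box,CD,L,Clay 1,R2,0.11,0.17,,0.7,
respirable,two_box,CD,L,Clay 1,R3,0.11,0.16,,0.7,
respirable,two_box,CD,L,Clay 2,R1,0.27,0.14,,1.9,
respirable,two_box,CD,L,Clay 2,R2,0.22,0.14,,1.6,
respirable,two_box,CD,L,Kaolin 1,R1,0.85,0.24,,3.5,
respirable,two_box,CD,L,Kaolin 1,R2,0.96,0.61,,1.6,
respirable,two_box,CD,M,Feldspar 1,R1,0.38,0.58,,0.7,
respirable,two_box,CD,M,Feldspar 1,R2,0.55,0.12,,4.6,
respirable,two_box,CD,M,Quartz 1,R1,0.26,0.15,,1.7,
respirable,two_box,CD,M,Quartz 1,R2,0.3,0.21,,1.4,
respirable,two_box,CD,H,Feldspar 2,R1,0.68,0.7,0.17,1.0,4.0
respirable,two_box,CD,H,Feldspar 2,R2,0.66,0.29,0.26,2.3,2.3
respirable,two_box,CD,H,Kaolin 2,R1,0.83,0.14,,6.1,
respirable,two_box,CD,H,Kaolin 2,R2,0.82,0.05,,15.0,
respirable,two_box,RD,L,Clay 1,R1,0.23,0.14,,1.6,
respirable,two_box,RD,L,Clay 1,R2,0.24,0.17,,1.4,
respirable,two_box,RD,L,Clay 1,R3,0.24,0.16,,1.5,
respirable,two_box,RD,L,Clay 2,R1,0.33,0.14,,2.4,
respirable,two_box,RD,L,Clay 2,R2,0.28,0.14,,2.1,
respirable,two_box,RD,L,Kaolin 1,R1,0.35,0.24,,1.4,
respirable,two_box,RD,L,Kaolin 1,R2,0.39,0.61,,0.6,
respirable,two_box,RD,M,Feldspar 1,R1,0.47,0.58,,0.8,
respirable,two_box,RD,M,Feldspar 1,R2,0.67,0.12,,5.6,
respirable,two_box,RD,M,Quartz 1,R1,0.44,0.15,,2.9,
respirable,two_box,RD,M,Quartz 1,R2,0.52,0.21,,2.5,
respirable,two_box,RD,H,Feldspar 2,R1,0.3,0.7,0.17,0.4,1.8
respirable,two_box,RD,H,Feldspar 2,R2,0.29,0.29,0.26,1.0,1.0
respirable,two_box,RD,H,Kaolin 2,R1,0.64,0.14,,4.7,
respirable,two_box,RD,H,Kaolin 2,R2,0.63,0.05,,12.0,
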
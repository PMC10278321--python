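needle,measurement,n_drops,total_mass_mg,duration_s,flow_rate_printed_ml_per_s,resistance_printed_cm_s_per_ml
22G Pajunk Sprotte,M1,10,573.60,25.5,0.0225,667.5
22G Pajunk Sprotte,M2,10,574.20,25.6,0.0224,668.6
22G Pajunk Sprotte,M3,10,590.80,26.3,0.0225,667.7
22G Braun Spinocan,M1,10,549.60,51.8,0.0106,1415.0
22G Braun Spinocan,M2,10,539.50,50.7,0.0106,1410.8
22G Braun Spinocan,M3,10,554.50,52.1,0.0107,1408.0
22G M. Schilling,M1,9,480.80,32.6,0.0147,1017.1
22G M. Schilling,M2,9,508.60,34.9,0.0146,1029.3
22G M. Schilling,M3,9,507.80,35.2,0.0144,1039.8
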
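needle,R_cm_s_per_ml,tau_s
Sprotte 24G Atraumatic,2413.41,142.9
Spinocan 22G Quincke,1421.05,66.7
BD 22G Quincke,1064.04,55.6
BD 22G Whitacre,907.56,38.5
Sprotte 22G Atraumatic,667.7,25
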
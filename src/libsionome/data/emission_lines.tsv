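# libsionome reference emission-line library, v1
# Strong persistent lines from the NIST Atomic Spectra Database (air wavelengths, nm).
# The CN violet-system band head is treated as a single pseudo-line.
feature_label	center_wavelength	relative_strength	is_molecular_band
C	247.856	1.0	0
Zn	213.857	1.0	0
Zn	481.053	0.6	0
P	253.561	1.0	0
P	255.326	0.8	0
Mn	403.076	1.0	0
Mn	279.482	0.7	0
Mg	285.213	1.0	0
Mg	518.360	0.5	0
Si	288.158	1.0	0
Fe	371.993	1.0	0
Fe	373.713	0.7	0
Ca	422.673	1.0	0
Ca	393.366	0.9	0
Ca	396.847	0.7	0
Al	396.152	1.0	0
Al	394.401	0.8	0
Na	588.995	1.0	0
Na	589.592	0.5	0
H	656.279	1.0	0
Li	670.776	1.0	0
K	766.490	1.0	0
K	769.896	0.6	0
O	777.194	1.0	0
N	746.831	1.0	0
N	868.028	0.6	0
CN	388.340	1.0	1
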
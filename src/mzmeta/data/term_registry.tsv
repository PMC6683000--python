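origin_key	instrument	term_label	source_path	display_order	required
miape	Q Exactive - Orbitrap_MS	Instrument model	Q Exactive - Orbitrap_MS/Model	10	true
miape	Q Exactive - Orbitrap_MS	Spray voltage (kV)	Ion source/Spray voltage [kV]	20	true
miape	Q Exactive - Orbitrap_MS	Capillary temperature (°C)	Ion source/Capillary temperature [°C]	30	false
miape	Q Exactive - Orbitrap_MS	Polarity	Tune/Polarity	40	true
miape	Q Exactive - Orbitrap_MS	MS1 resolution	Method/MS1/Resolution	50	true
miape	Q Exactive - Orbitrap_MS	MS1 AGC target	Method/MS1/AGC target	60	false
miape	Q Exactive - Orbitrap_MS	MS1 scan range (m/z)	Method/MS1/Scan range [m\/z]	70	true
miape	Q Exactive - Orbitrap_MS	MS2 resolution	Method/MS2/Resolution	80	true
miape	Q Exactive - Orbitrap_MS	Normalized collision energy	Method/MS2/Normalized collision energy	90	true
miape	Q Exactive - Orbitrap_MS	Isolation window (m/z)	Method/MS2/Isolation window [m\/z]	100	false
miape	Q Exactive - Orbitrap_MS	Data-dependent Top N	Method/MS2/Top N	110	false
miape	Q Exactive - Orbitrap_MS	Dynamic exclusion (s)	Method/MS2/Dynamic exclusion [s]	120	false
miape	Q Exactive - Orbitrap_MS	Collision gas	Method/MS2/Collision gas	130	true
miape	Thermo EASY-nLC	LC instrument model	Thermo EASY-nLC/Model	200	true
miape	Thermo EASY-nLC	Sample pickup volume (µl)	Sample pickup [µl]	210	false
miape	Thermo EASY-nLC	Column equilibration volume (µl)	Equilibration [µl]	220	false
miape	Thermo EASY-nLC	LC flow (nl/min)	Gradient/00/Flow [nl\/min]	230	false
miape	Thermo EASY-nLC	Gradient start %B	Gradient/00/%B	240	false
miape	Thermo EASY-nLC	Gradient final %B	Gradient/02/%B	250	false
miape	Thermo EASY-nLC	Column length (cm)	Column length [cm]	260	false
jpr	Q Exactive - Orbitrap_MS	Mass spectrometer	Q Exactive - Orbitrap_MS/Model	10	true
jpr	Q Exactive - Orbitrap_MS	Spray voltage (kV)	Ion source/Spray voltage [kV]	20	false
jpr	Q Exactive - Orbitrap_MS	MS1 resolution	Method/MS1/Resolution	30	true
jpr	Q Exactive - Orbitrap_MS	MS2 resolution	Method/MS2/Resolution	40	true
jpr	Q Exactive - Orbitrap_MS	Collision energy (NCE)	Method/MS2/Normalized collision energy	50	true
jpr	Q Exactive - Orbitrap_MS	Precursors per cycle (Top N)	Method/MS2/Top N	60	false
jpr	Thermo EASY-nLC	LC system	Thermo EASY-nLC/Model	100	true
jpr	Thermo EASY-nLC	Flow rate (nl/min)	Gradient/00/Flow [nl\/min]	110	false
jpr	Thermo EASY-nLC	Final gradient step time (min)	Gradient/02/Time [min]	120	false
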
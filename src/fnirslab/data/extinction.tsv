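# Molar extinction coefficients for hemoglobin (Prahl/Cope compiled spectrum)
# units: cm^-1 per mole/liter; converted to mm^-1 mM^-1 (x 1e-4) at load time
# wavelength_nm	eps_hbo	eps_hbr
660	319.6	3226.56
690	276.0	2051.96
730	450.0	1102.20
750	518.0	1405.24
760	586.0	1548.52
780	710.0	1075.44
805	830.0	735.84
830	974.0	693.04
850	1058.0	691.32
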
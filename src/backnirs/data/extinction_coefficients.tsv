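# Molar extinction coefficients of hemoglobin, base-10, in cm^-1 / (mol/L).
# Transcribed from the compilation by S. Prahl, "Optical absorption of
# hemoglobin" (Oregon Medical Laser Center, 1999), based on the data of
# W. B. Gratzer and N. Kollias.  Used in the modified Beer-Lambert law as
#   dOD(lambda) = [e_O2Hb(lambda)*dC_O2Hb + e_HHb(lambda)*dC_HHb] * d * DPF(lambda)
# with dC in mol/L and the source-detector distance d in cm.
wavelength_nm	o2hb	hhb
760	586.0	1548.52
850	1058.0	691.32
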
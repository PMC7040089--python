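# Molar extinction coefficients of human hemoglobin (decadic, cm^-1 M^-1),
# compiled values tabulated by S. Prahl (Oregon Medical Laser Center, 1999)
# from Gratzer and Kollias. Convert to natural-log mm^-1 uM^-1 with
# ln(10) * 1e-7.
wavelength_nm,eps_hbo2,eps_hb,units,source
760,586.36,1548.52,cm^-1 M^-1 (decadic),Prahl 1999 compilation
830,974.16,693.04,cm^-1 M^-1 (decadic),Prahl 1999 compilation
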
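# Molar extinction coefficients for the three imaging wavelengths, expressed as
# natural-log absorption per unit concentration: mm^-1 per mM (i.e. mu_a = eps * C).
# Hb / HbO2 converted from the standard tabulated base-10 molar extinction spectra
# (cm^-1 M^-1, Prahl-type compilation) via eps_natural = eps_10 * ln(10) * 1e-4.
# Melanin follows the broadband eumelanin power-law approximation
# eps_10(lambda) ~ 1.7e12 * lambda_nm^-3.48 cm^-1 M^-1, same conversion.
# The table is user-replaceable: any CSV with these columns is accepted.
wavelength_nm,eps_hb,eps_hbo2,eps_melanin
460,3.720149,7.646701,0.211967
540,10.728204,12.258042,0.121321
623,1.317539,0.205851,0.073764
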
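# Default hemoglobin molar extinction coefficients, L·mmol⁻¹·cm⁻¹.
# Values follow the widely used compiled in-vitro hemoglobin spectra
# (tabulated per nm in the optics literature); swap here to recalibrate
# the forward model without touching code.
#
# Channel order everywhere in the package: red, infrared, green.
wavelengths_nm: [660.0, 940.0, 530.0]
eps_hb:   [3.2266, 0.6934, 39.0364]   # deoxygenated hemoglobin (Hb)
eps_hbo2: [0.3198, 1.2140, 35.6784]   # oxygenated hemoglobin (HbO2)
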
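# Default acquisition geometry for visible-light SFDI of skin.
wavelengths_nm: [623, 540, 460]
fx_per_mm: 0.2
phases_deg: [0, 120, 240]
pixel_pitch_mm: 0.05
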
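# SIROF-like synthetic electrode circuit.
# Designed ground truth: anodic CSC 12 mC/cm2, cathodic CSC 17 mC/cm2
# (window -0.6..0.8 V), CIC 3.3 mC/cm2 (0.8 V anodic limit x 4.125 mF/cm2).
access_resistance_ohm: 50000.0
c_specific_F_cm2: 4.125e-3
cv_anodic:
  baseline_F_cm2: 6.0e-3           # 8.4 mC/cm2 over the 1.4 V window
  peaks:
    - {center_V: 0.1, width_V: 0.15, height_F_cm2: 9.575e-3}   # +3.6 mC/cm2
cv_cathodic:
  baseline_F_cm2: 8.0e-3           # 11.2 mC/cm2 over the window
  peaks:
    - {center_V: -0.1, width_V: 0.18, height_F_cm2: 12.855e-3} # +5.8 mC/cm2
noise_sd_V: 0.0
cv_noise_sd_A: 0.0
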
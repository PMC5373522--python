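# SYNTHETIC example coefficients for the 5-parameter A-ECG LVSD logistic score.
# These values are placeholders for unit testing and demonstration only; they were
# NOT taken from any published score and carry no clinical meaning. Supply the
# published coefficient file for real analyses.
intercept = -1.0
spatial_mean_qrst_angle = 0.02
z_qrs_integral = -0.01
total_qrs_voltage = -0.05
qrs_nondipolar_voltage = 8.0
t_dipolar_voltage = -4.0
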
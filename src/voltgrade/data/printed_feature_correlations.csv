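feature,corr_ca15_3,corr_muc1
median_current,-0.3161,-0.5413
peak_width_half_height,-0.0495,-0.4434
skewness,-0.4048,-0.2849
negative_peak_current,-0.0138,-0.1729
negative_peak_potential,0.2290,-0.0997
mean_current,-0.0620,-0.0591
half_peak_potential,-0.2592,-0.0427
peak_second_derivative,0.3321,-0.0270
std_current,0.1060,0.0976
charge_Q,0.0030,0.1402
positive_peak_current,0.1499,0.1865
positive_peak_potential,0.3297,0.2796
kurtosis,0.4627,0.2955
peak_derivative,0.3327,0.3608
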
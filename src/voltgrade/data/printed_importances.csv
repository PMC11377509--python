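rank,feature,importance_ca15_3,importance_muc1
1,kurtosis,0.1440,0.0868
2,skewness,0.1062,0.0863
3,median_current,0.0884,0.0878
4,peak_second_derivative,0.0880,0.0913
5,positive_peak_current,0.0832,0.0739
6,peak_derivative,0.0744,0.0835
7,negative_peak_current,0.0721,0.0720
8,charge_Q,0.0714,0.0985
9,std_current,0.0678,0.0860
10,mean_current,0.0618,0.0922
11,peak_width_half_height,0.0482,0.0590
12,positive_peak_potential,0.0348,0.0353
13,half_peak_potential,0.0327,0.0335
14,negative_peak_potential,0.0262,0.0132
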
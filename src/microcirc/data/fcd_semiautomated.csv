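subject,baseline_area,baseline_length,hemorrhage_area,hemorrhage_length
1,13.77,1.63e-5,9.72,9.52e-6
2,14.50,2.15e-5,7.32,1.47e-5
3,10.81,1.72e-5,11.39,1.62e-5
4,11.95,2.41e-5,6.68,1.91e-5
5,9.44,2.18e-5,9.21,9.65e-6
6,13.38,1.00e-5,7.47,8.29e-6
7,10.15,1.75e-5,8.36,1.43e-5
8,13.23,1.23e-5,8.06,8.22e-6
9,13.07,8.18e-6,8.82,8.04e-6
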
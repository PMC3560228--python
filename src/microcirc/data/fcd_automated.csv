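subject,baseline_area,baseline_length,hemorrhage_area,hemorrhage_length
1,12.16,2.35e-5,9.72,1.42e-5
2,14.99,3.35e-5,7.32,1.48e-5
3,13.97,3.10e-5,11.38,3.26e-5
4,11.95,2.56e-5,5.92,1.97e-5
5,10.21,3.10e-5,7.58,2.02e-5
6,13.81,3.75e-5,4.41,2.12e-5
7,11.90,4.01e-5,7.38,1.65e-5
8,13.49,4.04e-5,7.05,1.77e-5
9,11.65,3.11e-5,5.37,2.26e-5
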
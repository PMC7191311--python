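wavelength_nm,mu_a,mu_s_prime
405,176.03,2.53
532,23.43,2.11
595,3.89,1.96
632,0.39,1.88
694,0.19,1.77
755,0.32,1.68
800,0.44,1.61
980,0.59,1.41
1064,0.30,1.34
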
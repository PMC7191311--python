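tissue,wavelength_nm,mu_a_mean,mu_a_sd,mu_s_prime_mean,mu_s_prime_sd
epidermis,405,3.32,1.51,9.95,2.02
epidermis,532,1.44,0.69,7.04,1.48
epidermis,595,1.13,0.53,6.02,1.33
epidermis,632,0.94,0.41,5.55,1.25
epidermis,694,0.72,0.29,4.89,1.15
epidermis,755,0.49,0.19,4.28,1.04
epidermis,800,0.39,0.15,3.98,1.00
epidermis,980,0.17,0.09,3.17,0.85
epidermis,1064,0.13,0.10,2.85,0.86
dermis,405,0.43,0.10,6.46,1.77
dermis,532,0.10,0.03,3.96,0.89
dermis,595,0.07,0.02,3.35,0.71
dermis,632,0.07,0.02,3.06,0.62
dermis,694,0.06,0.02,2.64,0.53
dermis,755,0.05,0.01,2.20,0.43
dermis,800,0.05,0.01,2.01,0.39
dermis,980,0.07,0.01,1.45,0.29
dermis,1064,0.05,0.01,1.34,0.29
subcutaneous_fat,405,0.62,0.34,2.56,0.94
subcutaneous_fat,532,0.15,0.07,1.89,0.45
subcutaneous_fat,595,0.09,0.05,1.77,0.33
subcutaneous_fat,632,0.07,0.03,1.72,0.30
subcutaneous_fat,694,0.06,0.02,1.60,0.26
subcutaneous_fat,755,0.04,0.02,1.43,0.22
subcutaneous_fat,800,0.04,0.02,1.37,0.20
subcutaneous_fat,980,0.04,0.02,1.18,0.17
subcutaneous_fat,1064,0.03,0.02,1.11,0.16
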
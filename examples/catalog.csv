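name,n_frac,p_frac,k_frac,price_per_50kg
urea,0.46,0.0,0.0,4.3
dap,0.18,0.201,0.0,18.6
muriate_of_potash,0.0,0.0,0.498,12.7
ssp,0.0,0.07,0.0,5.9
17-17-17,0.17,0.074,0.141,14.3
20-20-0,0.2,0.087,0.0,14.3
zinc_sulfate,0.0,0.0,0.0,36.5
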
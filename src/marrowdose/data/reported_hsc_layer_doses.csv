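nuclide,group,model_gy_per_source,icrp60_gy_per_source,icrp103_gy_per_source
Cs-137,beta,7.67e-09,6.83e-09,8.41e-09
I-131,beta,4.26e-12,1.28e-11,4.01e-12
Sr-90,beta,1.96e-08,3.43e-08,3.92e-08
Ra-223,alpha,1.88e-10,3.92e-09,8.19e-10
Pu-239,alpha,1.32e-06,1.92e-05,3.23e-06
U-238,alpha,4.45e-10,9.70e-08,1.03e-08
Th-232,alpha,6.38e-07,2.26e-05,2.32e-06
Rn-222,alpha,1.69e-11,,
Xe-133,noble_gas,2.37e-13,,
Xe-135,noble_gas,3.63e-13,,
Kr-85,noble_gas,1.65e-13,,
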
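site,body_tissue_g,cortical_g,trabecular_g,soft_g,rbm_g,blood_g,blood_in_rbm_g
cervical_vertebra_01,0.8,,0.2,0.6,0.5,0.1,0.1
cervical_vertebra_02,7.1,,3.3,3.9,2.9,0.4,0.4
cervical_vertebra_03,40.7,13.7,8.6,18.3,13.7,2.2,1.8
cervical_vertebra_04,62.5,40,,22.5,16.9,2.8,2.3
cervical_vertebra_05,47.5,36.1,,11.4,8.5,1.6,1.2
cervical_vertebra_06,39.5,35.6,,4,3,,0.4
cervical_vertebra_07,8.6,8.6,,,,,
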
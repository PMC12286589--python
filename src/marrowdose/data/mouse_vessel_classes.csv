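class,n_segments,mean_diameter_um
arterial,9,8.0
postarterial_capillary,5,7.8
intermediate_capillary,6,11.2
sinusoid,31,21.1
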
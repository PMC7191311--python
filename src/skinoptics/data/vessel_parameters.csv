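plexus,center_depth_um,volume_fraction_pct,diameter_um
capillary,230,4,10
upper,340,30,50
deep,1210,10,80
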
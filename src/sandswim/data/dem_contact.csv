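parameter,value,units
hardness_k,2.0e6,N m^-3/2
viscoelastic_g_n,15.0,N s m^-3/2
mu_particle_particle,0.1,-
mu_body_particle,0.27,-
restitution,0.88,-
grain_density,2470.0,kg m^-3
diameter_small,3.0e-3,m
diameter_large,3.4e-3,m
large_fraction,0.5,-
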
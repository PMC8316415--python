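# Photon mass attenuation coefficients mu/rho [cm^2/g], fixture v1.
# Columns: energy_mev, soft_tissue, bone, air.
# Values follow the standard tabulated photon data for water-equivalent soft
# tissue, cortical bone and dry air on a log-energy grid (10 keV - 2 MeV).
# The engine splits each total into a Klein-Nishina Compton component
# (computed from the material electron density) and a residual local-absorption
# component (photoelectric-dominated).
energy_mev,soft_tissue,bone,air
0.010,5.100,28.51,5.120
0.015,1.580,9.032,1.614
0.020,0.7100,4.001,0.7779
0.030,0.3300,1.331,0.3538
0.040,0.2480,0.6655,0.2485
0.050,0.2140,0.4242,0.2080
0.060,0.1970,0.3148,0.1875
0.080,0.1790,0.2229,0.1662
0.100,0.1670,0.1855,0.1541
0.150,0.1490,0.1480,0.1356
0.200,0.1360,0.1309,0.1233
0.300,0.1180,0.1103,0.1067
0.500,0.0966,0.0926,0.0871
0.800,0.0786,0.0731,0.0706
1.000,0.0707,0.0657,0.0636
1.500,0.0575,0.0534,0.0517
2.000,0.0494,0.0459,0.0445
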
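# dipolemm force-field parameter file
# calibrated by dipolemm.calibrate.fit_parameters against the shipped reference set
bond C_co2 O_co2 ks 1043.0753440362669
bond C_co2 O_co2 r0 1.1599999999999999
bond C_co2 O_co2 mu 1.481823343742724
bond O_hydroxyl H_O ks 770
bond O_hydroxyl H_O r0 0.94699999999999995
bond O_hydroxyl H_O mu 3.0299900168392764
bond N_amine H_N ks 640
bond N_amine H_N r0 1.0149999999999999
bond N_amine H_N mu 0.69998967821824865
bond C_sp3 O_hydroxyl ks 540
bond C_sp3 O_hydroxyl r0 1.413
bond C_sp3 O_hydroxyl mu 0.10000160808269455
bond C_sp3 N_amine ks 510
bond C_sp3 N_amine r0 1.448
bond C_sp3 N_amine mu 1.4999970521164863
bond C_sp3 C_sp3 ks 450
bond C_sp3 C_sp3 r0 1.5249999999999999
bond C_sp3 C_sp3 mu 0
bond C_sp3 H_C ks 474
bond C_sp3 H_C r0 1.1120000000000001
bond C_sp3 H_C mu 0
angle O_co2 C_co2 O_co2 kb 49.283012823530179
angle O_co2 C_co2 O_co2 theta0 180
angle C_sp3 O_hydroxyl H_O kb 55
angle C_sp3 O_hydroxyl H_O theta0 106.90000000000001
angle C_sp3 C_sp3 C_sp3 kb 63
angle C_sp3 C_sp3 C_sp3 theta0 110.2
angle C_sp3 C_sp3 O_hydroxyl kb 70
angle C_sp3 C_sp3 O_hydroxyl theta0 107.5
angle C_sp3 C_sp3 N_amine kb 63
angle C_sp3 C_sp3 N_amine theta0 109.5
angle C_sp3 N_amine H_N kb 52
angle C_sp3 N_amine H_N theta0 112
angle H_N N_amine H_N kb 45
angle H_N N_amine H_N theta0 106.40000000000001
angle C_sp3 C_sp3 H_C kb 45
angle C_sp3 C_sp3 H_C theta0 110
angle H_C C_sp3 H_C kb 39
angle H_C C_sp3 H_C theta0 107.8
angle O_hydroxyl C_sp3 H_C kb 55
angle O_hydroxyl C_sp3 H_C theta0 108.90000000000001
angle N_amine C_sp3 H_C kb 52
angle N_amine C_sp3 H_C theta0 109.3
torsion C_sp3 C_sp3 v1 0.20000000000000001
torsion C_sp3 C_sp3 v2 0.29999999999999999
torsion C_sp3 C_sp3 v3 0.5
torsion C_sp3 O_hydroxyl v1 0.40000000000000002
torsion C_sp3 O_hydroxyl v2 0.5
torsion C_sp3 O_hydroxyl v3 0.40000000000000002
torsion C_sp3 N_amine v1 0
torsion C_sp3 N_amine v2 0
torsion C_sp3 N_amine v3 0.5
torsion N_amine C_sp3 C_sp3 O_hydroxyl v1 0.5
torsion N_amine C_sp3 C_sp3 O_hydroxyl v2 -0.5
torsion N_amine C_sp3 C_sp3 O_hydroxyl v3 0.69999999999999996
lj C_co2 rv 1.4952987324757481
lj C_co2 eps 0.027081517573957218
lj O_co2 rv 1.489366046643418
lj O_co2 eps 0.10274050122172664
lj C_sp3 rv 2.04
lj C_sp3 eps 0.027
lj N_amine rv 1.2999999839645524
lj N_amine eps 0.30000049531134476
lj O_hydroxyl rv 2.0300004139635783
lj O_hydroxyl eps 0.34000002515898248
lj H_C rv 1.6200000000000001
lj H_C eps 0.02
lj H_N rv 1.6000000000000001
lj H_N eps 0.0340000544982502
lj H_O rv 1.6000000000000001
lj H_O eps 0.0066084443629594175
global dielectric 1
global cut_vdw 10
global cut_dipole 12
global taper_width 1
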
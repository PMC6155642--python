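# Reference observables for calibrating the CO2/MEA bond-dipole potential.
# Energies in kcal/mol, frequencies in cm^-1, distances in angstrom.
# Interaction-energy benchmarks for the three (CO2)2 arrangements with their
# dipole-dipole (mumu) and Lennard-Jones decomposition; CO2 monomer normal
# modes; hydrogen-bonded (MEA)2 benchmarks (NHN and OHO, donor X-H...X angle
# frozen at 180 deg); CO2 binding at the amino and hydroxyl motifs of MEA;
# and the physisorption C(CO2)-N(MEA) equilibrium distance.
# Zero-weight context rows carry the corresponding quantum-chemistry binding
# energies (BLYP-D2 and MP2, counterpoise-corrected) for the same structures.
kind	recipe	target	units	weight	provenance
dimer_total	co2_min	-1.23	kcal/mol	3	benchmark table: (CO2)2 global minimum, MM interaction energy
dimer_component_mumu	co2_min	-1.00	kcal/mol	2	benchmark table: (CO2)2 minimum, dipole-dipole component
dimer_component_lj	co2_min	-0.23	kcal/mol	2	benchmark table: (CO2)2 minimum, LJ component
dimer_total	co2_parallel	0.16	kcal/mol	3	benchmark table: parallel (CO2)2, C-C frozen at 4.0 A
dimer_component_mumu	co2_parallel	0.32	kcal/mol	1	benchmark table: parallel (CO2)2, dipole-dipole component
dimer_component_lj	co2_parallel	-0.15	kcal/mol	1	benchmark table: parallel (CO2)2, LJ component
dimer_total	co2_T	-0.92	kcal/mol	3	benchmark table: T-type (CO2)2, MM interaction energy
dimer_component_mumu	co2_T	-0.70	kcal/mol	1	benchmark table: T-type (CO2)2, dipole-dipole component
dimer_component_lj	co2_T	-0.22	kcal/mol	1	benchmark table: T-type (CO2)2, LJ component
frequency	co2:bend	629	cm^-1	1	benchmark table: CO2 monomer bend (doubly degenerate)
frequency	co2:sym	1240	cm^-1	1	benchmark table: CO2 monomer symmetric stretch
frequency	co2:asym	2374	cm^-1	1	benchmark table: CO2 monomer antisymmetric stretch (prediction)
dimer_total	mea_NHN	-4.16	kcal/mol	3	benchmark table: (MEA)2 NHN, MM total interaction energy
dimer_component_mumu	mea_NHN	-2.17	kcal/mol	1	benchmark table: (MEA)2 NHN, dipole-dipole component
dimer_component_lj	mea_NHN	-1.99	kcal/mol	1	benchmark table: (MEA)2 NHN, vdW component
dimer_total	mea_OHO	-6.15	kcal/mol	4	benchmark table: (MEA)2 OHO, MM total interaction energy
dimer_component_mumu	mea_OHO	-4.33	kcal/mol	1	benchmark table: (MEA)2 OHO, dipole-dipole component
dimer_component_lj	mea_OHO	-1.82	kcal/mol	1	benchmark table: (MEA)2 OHO, vdW component
dimer_total	co2_mea_amino	-5.50	kcal/mol	3	interfacial study: CO2 at the amino motif, |Eint| = 5.50 at the MM level
dimer_total	co2_mea_hydroxyl	-5.05	kcal/mol	3	interfacial study: CO2 at the hydroxyl motif, |Eint| = 5.05 at the MM level
scan_minimum_distance	co2_mea_scan	2.7	angstrom	20	physisorption scan: relaxed C(CO2)-N(MEA) minimum near 2.7 A
context_qm	co2_min	-1.06	kcal/mol	0	context: BLYP-D2 binding energy, (CO2)2 minimum
context_qm	co2_min_mp2	-1.27	kcal/mol	0	context: MP2 binding energy, (CO2)2 minimum
context_qm	co2_parallel	0.25	kcal/mol	0	context: BLYP-D2 binding energy, parallel (CO2)2
context_qm	co2_parallel_mp2	-0.01	kcal/mol	0	context: MP2 binding energy, parallel (CO2)2
context_qm	co2_T	-0.77	kcal/mol	0	context: BLYP-D2 binding energy, T-type (CO2)2
context_qm	co2_T_mp2	-1.07	kcal/mol	0	context: MP2 binding energy, T-type (CO2)2
context_qm	mea_NHN	-4.62	kcal/mol	0	context: BLYP-D2 binding energy, (MEA)2 NHN
context_qm	mea_OHO	-6.90	kcal/mol	0	context: BLYP-D2 binding energy, (MEA)2 OHO
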
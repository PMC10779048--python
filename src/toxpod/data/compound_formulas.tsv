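compound	metal	metal_atoms	molar_mass_compound	molar_mass_metal
ZnO	Zn	1	81.3790	65.3800
NiO	Ni	1	74.6920	58.6930
Al2O3	Al	2	101.9600	26.9815
TiO2	Ti	1	79.8650	47.8670
CuO	Cu	1	79.5450	63.5460
ZnCl2	Zn	1	136.2800	65.3800
NiCl2.6H2O	Ni	1	237.6830	58.6930
AlCl3.6H2O	Al	1	241.4215	26.9815
CuCl2.2H2O	Cu	1	170.4760	63.5460
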
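name	formula	charge	phase	dGf0_kJ_mol	dHf0_kJ_mol	provenance
H2O	H2O	0	liquid	-237.18	-285.83	standard bioenergetics tables (Madigan; Thauer convention)
H+	H	1	aqueous	0	0	convention: 1 M proton standard state
HCO3-	CHO3	-1	aqueous	-586.85	-692.0	standard bioenergetics tables (Madigan; Thauer convention)
acetate	C2H3O2	-1	aqueous	-369.41	-486.01	standard bioenergetics tables (Thauer convention)
SO4-2	SO4	-2	aqueous	-744.6	-909.27	standard bioenergetics tables (CODATA-consistent)
HS-	HS	-1	aqueous	12.1	-17.6	standard bioenergetics tables (Thauer convention)
H2	H2	0	gas	0	0	element reference state
H2(aq)	H2	0	aqueous	17.6	-4.2	aqueous 1 M standard state (anaerobic-bioenergetics convention)
benzoate	C7H5O2	-1	aqueous	-245.6	-386.4055	dGf: aromatic-compound anaerobic-bioenergetics tables; dHf: back-derived from complete-oxidation scenario enthalpy
hexadecane(aq)	C16H34	0	aqueous	49.4725	-455.8525	back-derived from acetogenic-oxidation scenario energies (aqueous standard state)
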
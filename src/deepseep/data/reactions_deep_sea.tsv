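reaction_id	label	class	stoichiometry
r1	Hydrogenogenic oxidation of hexadecane	hydrogenogenic_oxidation	hexadecane(aq):-1;H2O:-16;acetate:8;H2(aq):17;H+:8
r2	Acetogenic oxidation of hexadecane	acetogenic_oxidation	hexadecane(aq):-1;HCO3-:-8.5;acetate:12.25;H+:3.75;H2O:1
r3	Complete oxidation of hexadecane	complete_oxidation	hexadecane(aq):-1;SO4-2:-12.25;HCO3-:16;HS-:12.25;H2O:1;H+:3.75
r4	Hydrogenogenic oxidation of benzoate	hydrogenogenic_oxidation	benzoate:-1;H2O:-7;acetate:3;HCO3-:1;H2(aq):3;H+:3
r5	Acetogenic oxidation of benzoate	acetogenic_oxidation	benzoate:-1;HCO3-:-0.5;acetate:3.75;H+:2.25
r6	Complete oxidation of benzoate	complete_oxidation	benzoate:-1;SO4-2:-3.75;H2O:-4;HCO3-:7;HS-:3.755;H+:2.25
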
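pathway	family_id	note
glycolysis_EMP	K00844	hexokinase/glucokinase
glycolysis_EMP	K01810	glucose-6-phosphate isomerase
glycolysis_EMP	K00850	6-phosphofructokinase
glycolysis_EMP	K01623	fructose-bisphosphate aldolase
glycolysis_EMP	K01803	triosephosphate isomerase
glycolysis_EMP	K00134	glyceraldehyde-3-phosphate dehydrogenase
glycolysis_EMP	K00927	phosphoglycerate kinase
glycolysis_EMP	K01834	phosphoglycerate mutase
glycolysis_EMP	K01689	enolase
glycolysis_EMP	K00873	pyruvate kinase
beta_oxidation	K01897	long-chain acyl-CoA synthetase
beta_oxidation	K00249	acyl-CoA dehydrogenase
beta_oxidation	K01692	enoyl-CoA hydratase
beta_oxidation	K00022	3-hydroxyacyl-CoA dehydrogenase
beta_oxidation	K00632	acetyl-CoA acyltransferase (thiolase)
wood_ljungdahl	K00198	anaerobic CO dehydrogenase (cooS/acsA)
wood_ljungdahl	K14138	acetyl-CoA synthase (acsB, diagnostic)
wood_ljungdahl	K00194	acetyl-CoA decarbonylase/synthase delta subunit
wood_ljungdahl	K00197	acetyl-CoA decarbonylase/synthase gamma subunit
wood_ljungdahl	K01938	formate--tetrahydrofolate ligase
wood_ljungdahl	K01491	methylenetetrahydrofolate dehydrogenase/cyclohydrolase
wood_ljungdahl	K00297	methylenetetrahydrofolate reductase
wood_ljungdahl	K15023	methyltetrahydrofolate corrinoid methyltransferase (acsE)
tca_cycle	K01647	citrate synthase
tca_cycle	K01681	aconitate hydratase
tca_cycle	K00031	isocitrate dehydrogenase
tca_cycle	K00164	2-oxoglutarate dehydrogenase E1
tca_cycle	K01902	succinyl-CoA synthetase alpha
tca_cycle	K01903	succinyl-CoA synthetase beta
tca_cycle	K00239	succinate dehydrogenase flavoprotein
tca_cycle	K01676	fumarate hydratase
tca_cycle	K00024	malate dehydrogenase
benzoyl_coa_pathway	K04112	benzoyl-CoA reductase subunit (bcrC)
benzoyl_coa_pathway	K04113	benzoyl-CoA reductase subunit (bcrB)
benzoyl_coa_pathway	K04114	benzoyl-CoA reductase subunit (bcrA)
benzoyl_coa_pathway	K04115	benzoyl-CoA reductase subunit (bcrD)
benzoyl_coa_pathway	K07537	cyclohexa-1,5-diene-1-carbonyl-CoA hydratase (dch)
benzoyl_coa_pathway	K07538	6-hydroxycyclohex-1-ene-1-carbonyl-CoA dehydrogenase (had)
benzoyl_coa_pathway	K07539	6-oxocyclohex-1-ene-carbonyl-CoA hydrolase (oah)
fumarate_addition	assA	alkylsuccinate synthase catalytic subunit
fumarate_addition	bssA	benzylsuccinate synthase catalytic subunit
lactate_fermentation	K00016	L-lactate dehydrogenase
ethanol_fermentation	K00001	alcohol dehydrogenase
sulfate_reduction	K11180	dissimilatory sulfite reductase alpha (dsrA)
sulfate_reduction	K11181	dissimilatory sulfite reductase beta (dsrB)
organohalide_respiration	rdhA	reductive dehalogenase catalytic subunit
hydrogenase_FeFe_A	FeFe-A	group A [FeFe]-hydrogenase
hydrogenase_NiFe_1	NiFe-1	group 1 respiratory [NiFe]-hydrogenase
hydrogenase_NiFe_3b	NiFe-3b	group 3b bidirectional [NiFe]-hydrogenase
hydrogenase_NiFe_3c	NiFe-3c	group 3c electron-bifurcating [NiFe]-hydrogenase
hydrogenase_NiFe_3d	NiFe-3d	group 3d bidirectional [NiFe]-hydrogenase
hydrogenase_NiFe_4	NiFe-4	group 4 H2-evolving [NiFe]-hydrogenase
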
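record_type	id	name	carbons	nitrogens	role	compartment	genes	block	step_weight	stoich	cofactor_delta
metabolite	glc	glucose	6	0	boundary	cytosol					
metabolite	co2	carbon dioxide	1	0	boundary	unassigned					
metabolite	h2o	water	0	0	boundary	unassigned					
metabolite	pi	inorganic phosphate	0	0	boundary	unassigned					
metabolite	nh3	ammonia	0	1	boundary	unassigned					
metabolite	g6p	glucose-6-phosphate	6	0	intermediate	cytosol					
metabolite	f6p	fructose-6-phosphate	6	0	intermediate	cytosol					
metabolite	f16bp	fructose-1,6-bisphosphate	6	0	intermediate	cytosol					
metabolite	dhap	dihydroxyacetone phosphate	3	0	intermediate	cytosol					
metabolite	g3p	glyceraldehyde-3-phosphate	3	0	intermediate	cytosol					
metabolite	bpg13	1,3-bisphosphoglycerate	3	0	intermediate	cytosol					
metabolite	pg3	3-phosphoglycerate	3	0	intermediate	cytosol					
metabolite	pg2	2-phosphoglycerate	3	0	intermediate	cytosol					
metabolite	pep	phosphoenolpyruvate	3	0	intermediate	cytosol					
metabolite	pyr	pyruvate	3	0	intermediate	cytosol					
metabolite	accoa	acetyl-CoA (acetyl unit)	2	0	intermediate	mitochondrion					
metabolite	oaa	oxaloacetate	4	0	intermediate	mitochondrion					
metabolite	cit	citrate	6	0	intermediate	mitochondrion					
metabolite	icit	isocitrate	6	0	intermediate	mitochondrion					
metabolite	akg	alpha-ketoglutarate	5	0	intermediate	mitochondrion					
metabolite	succoa	succinyl-CoA (succinyl unit)	4	0	intermediate	mitochondrion					
metabolite	succ	succinate	4	0	intermediate	mitochondrion					
metabolite	fum	fumarate	4	0	intermediate	mitochondrion					
metabolite	mal	malate	4	0	intermediate	mitochondrion					
metabolite	glu	glutamate	5	1	intermediate	unassigned					
metabolite	php	3-phosphohydroxypyruvate	3	0	intermediate	cytosol					
metabolite	pser	3-phosphoserine	3	1	intermediate	cytosol					
metabolite	ser	serine	3	1	intermediate	unassigned					
metabolite	gly	glycine	2	1	intermediate	mitochondrion					
metabolite	thf	tetrahydrofolate	0	0	intermediate	unassigned					
metabolite	mlthf	5,10-methylene-THF	1	0	intermediate	unassigned					
metabolite	methf	5,10-methenyl-THF	1	0	intermediate	unassigned					
metabolite	fthf	10-formyl-THF	1	0	intermediate	unassigned					
metabolite	formate	formate	1	0	intermediate	unassigned					
metabolite	pgl6	6-phosphogluconolactone	6	0	intermediate	cytosol					
metabolite	pg6	6-phosphogluconate	6	0	intermediate	cytosol					
metabolite	ru5p	ribulose-5-phosphate	5	0	intermediate	cytosol					
metabolite	r5p	ribose-5-phosphate	5	0	intermediate	cytosol					
metabolite	xu5p	xylulose-5-phosphate	5	0	intermediate	cytosol					
metabolite	e4p	erythrose-4-phosphate	4	0	intermediate	cytosol					
metabolite	s7p	sedoheptulose-7-phosphate	7	0	intermediate	cytosol					
reaction	HK	hexokinase				cytosol	HK1,HK2	glycolysis_partial	1	glc:-1;g6p:1	ATP:-1
reaction	GPI	glucose-6-phosphate isomerase				cytosol	GPI	glycolysis_partial	1	g6p:-1;f6p:1	
reaction	PFK	phosphofructokinase-1				cytosol	PFKL,PFKM,PFKP	glycolysis_partial	1	f6p:-1;f16bp:1	ATP:-1
reaction	ALDO	fructose-bisphosphate aldolase				cytosol	ALDOA	glycolysis_partial	1	f16bp:-1;dhap:1;g3p:1	
reaction	TPI	triosephosphate isomerase				cytosol	TPI1	glycolysis_partial	1	dhap:-1;g3p:1	
reaction	GAPDH	glyceraldehyde-3-phosphate dehydrogenase				cytosol	GAPDH	glycolysis_partial	1	g3p:-1;bpg13:1	NADH:1
reaction	PGK	phosphoglycerate kinase				cytosol	PGK1	glycolysis_partial	1	bpg13:-1;pg3:1	ATP:1
reaction	PGM	phosphoglycerate mutase				cytosol	PGAM1	glycolysis_partial	1	pg3:-1;pg2:1	
reaction	ENO	enolase				cytosol	ENO1	glycolysis_partial	1	pg2:-1;pep:1	
reaction	PK	pyruvate kinase				cytosol	PKM	glycolysis_partial	1	pep:-1;pyr:1	ATP:1
reaction	PHGDH	phosphoglycerate dehydrogenase				cytosol	PHGDH	serinogenesis	1	pg3:-1;php:1	NADH:1
reaction	PSAT1	phosphoserine aminotransferase				cytosol	PSAT1	serinogenesis	1	php:-1;glu:-1;pser:1;akg:1	
reaction	PSPH	phosphoserine phosphatase				cytosol	PSPH	serinogenesis	1	pser:-1;ser:1	
reaction	GDH	glutamate dehydrogenase (NADH-dependent amination, glutamate recycling)				mitochondrion	GLUD1	serinogenesis	0	akg:-1;nh3:-1;glu:1	NADH:-1
reaction	SFXN1	sideroflexin-1 serine transport (mitochondrial import)				mitochondrion	SFXN1	transport	0		
reaction	SHMT2	serine hydroxymethyltransferase 2				mitochondrion	SHMT2	folate_cycling	1	ser:-1;thf:-1;gly:1;mlthf:1	
reaction	MTHFD2_DH	methylene-THF dehydrogenase (MTHFD2, NADP-dependent mode)				mitochondrion	MTHFD2	folate_cycling	1	mlthf:-1;methf:1	NADPH:1
reaction	MTHFD2_CH	methenyl-THF cyclohydrolase (MTHFD2)				mitochondrion	MTHFD2	folate_cycling	1	methf:-1;fthf:1	
reaction	ALDH1L2	10-formyl-THF dehydrogenase, mitochondrial				mitochondrion	ALDH1L2	folate_cycling	1	fthf:-1;thf:1;co2:1	NADPH:1
reaction	MTHFD2_DH_NAD	methylene-THF dehydrogenase (MTHFD2, NAD-dependent mode; variant excluded from the default shunt pathway)				mitochondrion	MTHFD2	folate_cycling	1	mlthf:-1;methf:1	NADH:1
reaction	MTHFD1L	10-formyl-THF synthetase, mitochondrial (formate-releasing direction)				mitochondrion	MTHFD1L	folate_cycling	1	fthf:-1;formate:1;thf:1	ATP:1
reaction	FORMATE_EXPORT	mitochondrial formate export				cytosol		transport	0		
reaction	MTHFD1	10-formyl-THF synthetase, cytosolic (formate re-fixation)				cytosol	MTHFD1	folate_cycling	1	formate:-1;thf:-1;fthf:1	ATP:-1
reaction	ALDH1L1	10-formyl-THF dehydrogenase, cytosolic				cytosol	ALDH1L1	folate_cycling	1	fthf:-1;thf:1;co2:1	NADPH:1
reaction	GCS	glycine cleavage system (aggregate, one step)				mitochondrion	GLDC,AMT,GCSH,DLD	glycine_cleavage	1	gly:-1;thf:-1;mlthf:1;co2:1;nh3:1	NADH:1
reaction	PDH	pyruvate dehydrogenase complex (aggregate, one step)				mitochondrion	PDHA1,PDHB,DLAT,DLD	pdh	1	pyr:-1;accoa:1;co2:1	NADH:1
reaction	CS	citrate synthase				mitochondrion	CS	cac	1	accoa:-1;oaa:-1;cit:1	
reaction	ACO	aconitase				mitochondrion	ACO2	cac	1	cit:-1;icit:1	
reaction	IDH3	isocitrate dehydrogenase (NAD-dependent)				mitochondrion	IDH3A,IDH3B,IDH3G	cac	1	icit:-1;akg:1;co2:1	NADH:1
reaction	OGDH	alpha-ketoglutarate dehydrogenase				mitochondrion	OGDH,DLST,DLD	cac	1	akg:-1;succoa:1;co2:1	NADH:1
reaction	SUCLG	succinyl-CoA synthetase (GTP booked as ATP)				mitochondrion	SUCLG1,SUCLG2	cac	1	succoa:-1;succ:1	ATP:1
reaction	SDH	succinate dehydrogenase				mitochondrion	SDHA,SDHB	cac	1	succ:-1;fum:1	FADH2:1
reaction	FH	fumarase				mitochondrion	FH	cac	1	fum:-1;mal:1	
reaction	MDH2	malate dehydrogenase, mitochondrial				mitochondrion	MDH2	cac	1	mal:-1;oaa:1	NADH:1
reaction	G6PD	glucose-6-phosphate dehydrogenase				cytosol	G6PD	ppp	1	g6p:-1;pgl6:1	NADPH:1
reaction	PGLS	6-phosphogluconolactonase				cytosol	PGLS	ppp	1	pgl6:-1;pg6:1	
reaction	PGD	6-phosphogluconate dehydrogenase				cytosol	PGD	ppp	1	pg6:-1;ru5p:1;co2:1	NADPH:1
reaction	RPI	ribose-5-phosphate isomerase				cytosol	RPIA	ppp	1	ru5p:-1;r5p:1	
reaction	RPE	ribulose-5-phosphate epimerase				cytosol	RPE	ppp	1	ru5p:-1;xu5p:1	
reaction	TKT1	transketolase (Xu5P + R5P -> S7P + G3P)				cytosol	TKT	ppp	1	xu5p:-1;r5p:-1;s7p:1;g3p:1	
reaction	TALDO	transaldolase				cytosol	TALDO1	ppp	1	s7p:-1;g3p:-1;e4p:1;f6p:1	
reaction	TKT2	transketolase (Xu5P + E4P -> F6P + G3P; same enzyme as TKT1, counted once)				cytosol	TKT	ppp	0	xu5p:-1;e4p:-1;f6p:1;g3p:1	
reaction	TPI_GN	triosephosphate isomerase (gluconeogenic direction)				cytosol	TPI1	ppp	1	g3p:-1;dhap:1	
reaction	ALDO_GN	fructose-bisphosphate aldolase (condensation direction)				cytosol	ALDOA	ppp	1	dhap:-1;g3p:-1;f16bp:1	
reaction	FBP1	fructose-1,6-bisphosphatase				cytosol	FBP1	ppp	1	f16bp:-1;f6p:1	
reaction	GPI_GN	glucose-6-phosphate isomerase (gluconeogenic direction)				cytosol	GPI	ppp	1	f6p:-1;g6p:1	
reaction	FAC	fatty acid cycling (aggregate of concurrent synthesis and beta-oxidation; net redox effect NADPH -> FADH2, 1:1)				cytosol	FASN,CPT1A,ACADVL,HADHA	fatty_acid_cycling	0		NADPH:-1;FADH2:1
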
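# Published normalized 2DE spot quantities for proteins present predominantly in
# Ciona intestinalis branchial cilia or sperm flagella (comparative axonemal
# proteomics worked example). Quantities are normalized spot quantities; the
# printed flagella/cilia ratio (f/c) carries "-" where one side was not detected.
predominant_in	category	q_flagella	q_cilia	fc_printed	protein
cilia	Cytoskeleton	0	121190	-	alpha-tubulin (TUBA3)
cilia	Cytoskeleton	0	95323	-	beta-tubulin (TUBB2)
cilia	Cytoskeleton	0	30071	-	actin (Ci-CA7)
cilia	Other axonemal structures	0	141373	-	tektin 3
cilia	Signaling and regulation	0	1827	-	calreticulin
cilia	Signaling and regulation	0	31057	-	heat shock protein 70 cognate
cilia	Signaling and regulation	0	8047	-	protein disulfide isomerase (pdi-2)
cilia	Signaling and regulation	0	2752	-	similar to protein disulfide isomerase
cilia	Signaling and regulation	0	698	-	fascin
cilia	Metabolism	0	4568	-	fumarylacetoacetase
cilia	Metabolism	0	1265	-	glutamate dehydrogenase 1
cilia	Metabolism	0	14186	-	transglutaminase
cilia	Uncharacterized proteins	0	1798	-	complement component C3
cilia	Uncharacterized proteins	0	3732	-	elongation factor 2
cilia	Uncharacterized proteins	1743	20944	0.08	tetratricopeptide repeat protein 29
cilia	Uncharacterized proteins	0	29892	-	EF-hand domain-containing family member B
cilia	Uncharacterized proteins	0	15844	-	78 kDa glucose-regulated protein
cilia	Uncharacterized proteins	0	9910	-	chromosome 6 open reading frame 97
flagella	Outer arm dynein	57429	0	-	axonemal p66.0 (Axp66.0)
flagella	Outer arm dynein	9122	0	-	DC2-related dynein intermediate chain 5
flagella	Outer arm dynein	84248	14812	5.69	calaxin
flagella	Cytoskeleton	596202	0	-	alpha-tubulin (TUBA3)
flagella	Cytoskeleton	360411	0	-	beta-tubulin (TUBB2)
flagella	Cytoskeleton	40638	0	-	actin (Ci-CA8)
flagella	Other axonemal structures	2130	0	-	tektin-like (TD20)
flagella	Other axonemal structures	1667	0	-	ODF3 (Shippo1) (TD11)
flagella	Other axonemal structures	2528	0	-	kinesin-like protein KIF9 isoform 2
flagella	Other axonemal structures	13134	0	-	no hit found (TD01)
flagella	Other axonemal structures	37375	4432	8.43	armadillo repeat containing 3 (ARM94)
flagella	Signaling and regulation	2256	0	-	cAMP-dependent protein kinase, Calpha
flagella	Signaling and regulation	77022	0	-	cAMP-dependent protein kinase, R II, alpha A
flagella	Signaling and regulation	9944	0	-	enkurin, TRPC channel interacting protein
flagella	Signaling and regulation	12708	0	-	rab GDP dissociation inhibitor alpha
flagella	Signaling and regulation	2118	0	-	TSSK2 (TD12)
flagella	Signaling and regulation	17795	0	-	apoptosis-inducing factor 2
flagella	Metabolism	23866	3111	7.67	phosphoglucose isomerase
flagella	Metabolism	9912	0	-	transketolase
flagella	Metabolism	4910	0	-	aconitate hydratase, mitochondrial
flagella	Metabolism	109021	19368	5.63	glyceraldehyde-3-phosphate dehydrogenase
flagella	Metabolism	4373	0	-	Cyt b-c1 complex subunit 2
flagella	Metabolism	21451	1294	16.58	phosphoglycerate kinase
flagella	Metabolism	2422	0	-	isocitrate dehydrogenase 3 (NAD+) alpha
flagella	Metabolism	864	0	-	glucose-6-phosphate dehydrogenase
flagella	Metabolism	4094	0	-	isocitrate dehydrogenase 3 (NAD+) beta
flagella	Metabolism	3216	0	-	glutamate dehydrogenase (NADP(+))
flagella	Metabolism	6068	0	-	prolyl-tRNA synthetase isoform 1
flagella	Metabolism	52429	1029	50.96	glycerol-3-phosphate dehydrogenase 1b
flagella	Metabolism	15338	0	-	alpha-enolase
flagella	Metabolism	4085	0	-	6-phosphofructokinase, muscle type
flagella	Metabolism	2364	0	-	adenylate kinase isoenzyme 1
flagella	Metabolism	8064	0	-	glycogen phosphorylase
flagella	Metabolism	134589	1833	73.43	fructose bisphosphate aldolase
flagella	Metabolism	6017	0	-	glutaredoxin-1
flagella	Metabolism	18742	764	24.55	creatine kinase Mt-CK3
flagella	Metabolism	35321	2580	13.69	Phosphoglycerate mutase 1
flagella	Metabolism	13334	863	15.44	Purine nucleoside phosphorylase
flagella	Metabolism	28953	3977	7.28	pyruvate kinase, muscle
flagella	Uncharacterized proteins	2256	0	-	similar to predicted protein
flagella	Uncharacterized proteins	23754	0	-	similar to RIKEN cDNA 1700009P17
flagella	Uncharacterized proteins	27148	2089	13.00	similar to predicted protein (2)
flagella	Uncharacterized proteins	1553	0	-	EH domain-containing protein 1
flagella	Uncharacterized proteins	47650	0	-	similar to Uncharacterized protein C13orf26
flagella	Uncharacterized proteins	3386	0	-	similar to leucine rich repeat containing 51
flagella	Uncharacterized proteins	1538	0	-	similar to predicted protein (3)
flagella	Uncharacterized proteins	27376	0	-	EF-hand domain-containing family member B
flagella	Uncharacterized proteins	6169	0	-	leucine rich repeat containing 34
flagella	Uncharacterized proteins	34458	0	-	armadillo repeat containing 4
flagella	Uncharacterized proteins	8183	0	-	similar to MORN repeat containing 5
flagella	Uncharacterized proteins	1022	0	-	growth arrest-specific 8
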
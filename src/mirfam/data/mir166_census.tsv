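# miR166 family census: per-species precursor and mature counts (miRBase-derived), 49 species.
species_name	abbreviation	division	clade_family	monocot_dicot	n_precursor	n_mature
Physcomitrella patens	ppt	bryophyta	Funariaceae	na	13	13
Selaginella moellendorffii	smo	fern	Selaginellaceae	na	3	3
Cunninghamia lanceolata	cln	gymnosperm	Cupressaceae	na	1	1
Picea abies	pab	gymnosperm	Pinaceae	na	10	10
Pinus densata	pde	gymnosperm	Pinaceae	na	2	2
Pinus taeda	pta	gymnosperm	Pinaceae	na	3	3
Amborella trichopoda	atr	angiosperm	Amborellaceae	base	4	4
Asparagus officinalis	aof	angiosperm	Asparagales	monocot	4	4
Vriesea carinata	vca	angiosperm	Bromeliaceae	monocot	3	6
Brachypodium distachyon	bdi	angiosperm	Poaceae	monocot	10	18
Aegilops tauschii	ata	angiosperm	Poaceae	monocot	5	10
Festuca arundinaceous	far	angiosperm	Poaceae	monocot	1	1
Sorghum bicolor	sbi	angiosperm	Poaceae	monocot	11	11
Zea mays	zma	angiosperm	Poaceae	monocot	14	26
Saccharum sp	ssp	angiosperm	Poaceae	monocot	1	1
Oryza sativa	osa	angiosperm	Poaceae	monocot	14	24
Hordeum vulgare	hvu	angiosperm	Poaceae	monocot	3	3
Aquilegia caerulea	aqc	angiosperm	Ranunculaceae	dicot	5	5
Vitis vinifera	vvi	angiosperm	Vitaceae	dicot	8	8
Glycine max	gma	angiosperm	Leguminosae	dicot	21	26
Lotus japonicus	lja	angiosperm	Leguminosae	dicot	1	1
Medicago truncatula	mtr	angiosperm	Leguminosae	dicot	8	10
Phaseolus vulgaris	pvu	angiosperm	Leguminosae	dicot	1	1
Fragaria vesca	fve	angiosperm	Rosaceae	dicot	6	7
Malus domestica	mdm	angiosperm	Rosaceae	dicot	10	10
Prunus persica	ppe	angiosperm	Rosaceae	dicot	5	5
Cucumis melo	cme	angiosperm	Cucurbitaceae	dicot	9	9
Populus trichocarpa	ptc	angiosperm	Salicaceae	dicot	17	17
Ricinus communis	rco	angiosperm	Euphorbiaceae	dicot	5	5
Linum usitatissimum	lus	angiosperm	Linaceae	dicot	11	11
Eugenia uniflora	eun	angiosperm	Myrtaceae	dicot	1	2
Citrus reticulata	crt	angiosperm	Rutaceae	dicot	2	2
Citrus sinensis	csi	angiosperm	Rutaceae	dicot	13	24
Citrus trifoliata	ctr	angiosperm	Rutaceae	dicot	1	1
Gossypium hirsutum	ghr	angiosperm	Malvaceae	dicot	1	1
Gossypium raimondii	gra	angiosperm	Malvaceae	dicot	2	2
Theobroma cacao	tcc	angiosperm	Malvaceae	dicot	4	4
Carica papaya	cpa	angiosperm	Caricaceae	dicot	5	5
Arabidopsis lyrata	aly	angiosperm	Cruciferae	dicot	8	16
Arabidopsis thaliana	ath	angiosperm	Cruciferae	dicot	7	10
Brassica napus	bna	angiosperm	Cruciferae	dicot	6	9
Camelina sativa	cas	angiosperm	Cruciferae	dicot	6	8
Nicotiana tabacum	nta	angiosperm	Solanaceae	dicot	8	8
Solanum lycopersicum	sly	angiosperm	Solanaceae	dicot	3	4
Solanum tuberosum	stu	angiosperm	Solanaceae	dicot	4	7
Digitalis purpurea	dpr	angiosperm	Plantaginaceae	dicot	2	2
Salvia sclarea	ssl	angiosperm	Labiatae	dicot	2	2
Helianthus paradoxus	hpa	angiosperm	Asteraceae	dicot	1	1
Helianthus petiolaris	hpe	angiosperm	Asteraceae	dicot	1	1
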
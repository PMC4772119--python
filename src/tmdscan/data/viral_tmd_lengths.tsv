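# Published per-protein TMD lengths of viral membrane proteins, grouped by
# animal-virus entry pathway (PM, CME, MPE, CAME) and plant-virus replication
# site (ER, Mitochondria, Peroxisome, Chloroplast, Nucleus).
# kingdom: animal = entry-pathway groups, plant = replication-site groups.
virus	protein	kingdom	group	tmd_length
HIV	gp41	animal	PM	30
Herpes_Simplex	gH	animal	PM	28
Measles	Hemagglutinin	animal	PM	30
Sendai	Fusion_protein	animal	PM	25
Hepatitis_C	E2	animal	CME	17
Sindbis	E1	animal	CME	5
Vesicular_Stomatitis	G	animal	CME	7
Semliki_Forest	E1	animal	CME	15
Equine_Infectious_Anemia	OMP	animal	CME	10
Vaccinia	A21	animal	MPE	8
Filamentous_Influenza	Hemagglutinin	animal	MPE	27
Cytomegalovirus	gH	animal	MPE	20
Respiratory_Syncytial_A	F1	animal	MPE	27
African_Swine_Fever	177L	animal	MPE	19
Ebola	Env_glycoprotein	animal	MPE	23
SV40	Agnoprotein	animal	CAME	10
Polyoma	Agnoprotein	animal	CAME	10
New_Castle_Disease	F1	animal	CAME	25
Echovirus_1	Capsid	animal	CAME	10
Potato_mop-top	TGBp2	plant	ER	20
Tomato-ringspot	X2	plant	ER	20
Tobacco-etch	6K2	plant	ER	20
Potato_Virus_X	TGBp3	plant	ER	20
Maize_Dwarf_Mosaic	6K2	plant	ER	19
Turnip_Mosaic	6K2	plant	ER	20
Flock_house	Protein_A	plant	Mitochondria	20
Carnation_Italian_Ringspot	RAP1	plant	Mitochondria	21
Pelargonium_Flower_Break	p27	plant	Mitochondria	21
Tomato_Bushy_Stunt	p33	plant	Peroxisome	21
Cymbidium_Ringspot	Movement_protein	plant	Peroxisome	23
Cucumber_Necrosis	p33	plant	Peroxisome	21
Turnip_Yellow_Mosaic	Methyl_transferase	plant	Chloroplast	11
Cowpea_chlorotic_mottle	Coat_protein	plant	Chloroplast	15
Sonchus_Yellow_Net	M2	plant	Nucleus	20
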
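# Reference context: the published allergen-database screen of the cacao PR-10
# query (report schema and motif/length layout). E-value, PD and identity columns
# come from the original database server and are reference context only — this
# package does not claim to regenerate them (server aligner internals unstated).
# motifs: semicolon-separated motif@subject_start entries (1-based).
allergen	species	description	accession	length	motifs	evalue	pd	identity
Que a 1.0101	Quercus alba	Major oak pollen allergen	P85126	50	DSDNLI@25	1.5e-07	6.13	17.72
Rub i 1.0101	Rubus idaeus	Putative allergen	Q0Z8U9	137	GDGGVG@38	3.8e-25	13.70	43.04
Dau c 1.0201	Daucus carota	Food allergen	AAL76932	154	GDGGVG@47	8.1e-18	13.66	35.44
Pet c PR10	Petroselinum crispum	Pathogenesis-related protein 1	CAA67246	155	GDGGVG@47	9.7e-21	13.94	39.87
Act d 8.0101	Actinidia deliciosa	Bet v 1 related food allergen	CAM31909	157	GDGGVG@47;EEEIKAGK@131	4.3e-24	12.13	48.73
Tar o RAP	Taraxacum officinale	Root and pathogenesis-related protein	AAB92255	157	GDGGVG@47	9.3e-18	16.21	35.44
Api g 1.0201	Apium graveolens	Food allergen	P92918	159	GDGGVG@47	3.9e-21	13.62	38.61
Mal d 1	Malus domestica	Food allergen	CAA96534	159	GDGGVG@47;TSHYHT@117	1.5e-30	12.67	53.16
Mal d 1	Malus domestica	Food allergen	CAA96535	160	GDGGVG@47	1.7e-28	13.39	54.43
Mal d 1	Malus domestica	Food allergen	CAA96536	160	GDGGVG@47	1.9e-28	13.34	53.80
Mal d 1	Malus domestica	Food allergen	CAA96537	160	GDGGVG@47	1.9e-28	13.22	54.43
Pru ar 1	Prunus armeniaca	Food allergen	O50001	160	GDGGVG@47;TSHYHT@118	7.4e-31	13.12	53.80
Pru p 1.0101	Prunus persica	Food allergen and PR-10	Q2I6V8	160	TSHYHT@118	2.1e-29	13.38	51.90
Pru av 1	Prunus avium	Food allergen	O24248	160	TSHYHT@118	5.5e-29	13.30	51.27
Bet v 1.1301	Betula verrucosa	Major pollen allergen	CAA54696	160	FPEGSHFK@59;EEEIKAGK@131	3.9e-30	13.46	54.43
Cor a 1.0401	Corylus avellana	Bet v 1-related major hazelnut allergen	AAD48405	161	EEEIKAGK@132	3.3e-26	14.31	49.37
Cor a 1.0404	Corylus avellana	Bet v 1-related major hazelnut allergen	AAG40331	161	EEEIKAGK@132	5.0e-26	14.25	48.73
Cor a 1.0403	Corylus avellana	Bet v 1-related major hazelnut allergen	AAG40330	161	EEEIKAGK@132	2.2e-26	14.34	50.00
Cor a 1.0402	Corylus avellana	Bet v 1-related major hazelnut allergen	AAG40329	161	EEEIKAGK@132	1.4e-26	13.56	50.00
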
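locus_tag	stress	phase	protein_log2fc	annotation	transcript_direction
SiRe_1208	acid	mid_log	2.08	Ornithine carbamoyltransferase	none
SiRe_2064	acid	mid_log	-3.01	Conserved hypothetical protein	up
SiRe_0753	acid	mid_log	-2.29	Ketol-acid reductoisomerase	none
SiRe_2623	acid	early_stationary	2.98	UDP-sulfoquinovose synthase, Agl3	down
SiRe_2451	acid	early_stationary	2.38	AMP-dependent synthetase and ligase	down
SiRe_2246	acid	early_stationary	1.94	Mandelate racemase (MR) subfamily	none
SiRe_0032	acid	early_stationary	1.62	Aminotransferase class V	down
SiRe_2599	acid	early_stationary	1.17	Conserved hypothetical protein	down
SiRe_2391	acid	early_stationary	1.15	Conserved hypothetical protein	up
SiRe_2464	acid	early_stationary	-3.31	Formate dehydrogenase, alpha subunit	up
SiRe_1684	acid	early_stationary	-2.58	Thioredoxin/glutaredoxin-like protein	none
SiRe_2601	acid	early_stationary	-2.19	Heat shock protein (Hsp20)	down
SiRe_1716	acid	early_stationary	-2.11	Thermosome	up
SiRe_1214	acid	early_stationary	-2.01	Thermosome	up
SiRe_1119	acid	early_stationary	-1.81	Deoxyhypusine synthase	up
SiRe_1633	acid	early_stationary	-1.70	Glutamine synthetase, type I	none
SiRe_0989	acid	early_stationary	-1.61	CoA-binding domain protein	down
SiRe_2064	acid	early_stationary	-1.59	Conserved hypothetical protein	down
SiRe_1066	acid	early_stationary	-1.57	Extracellular solute-binding protein family 1	down
SiRe_1444	cold	mid_log	1.22	A-type ATPase subunit, AtpI	none
SiRe_1371	cold	mid_log	-2.83	Arginosuccinate lyase	none
SiRe_0753	cold	mid_log	-2.19	Ketol-acid reductoisomerase	none
SiRe_0511	cold	mid_log	-1.44	Glycerol kinase	none
SiRe_2202	cold	mid_log	-1.29	Beta-glucosidase	none
SiRe_0643	cold	mid_log	-1.08	Amidohydrolase	none
SiRe_0099	cold	early_stationary	1.85	Short-chain dehydrogenase/reductase SDR	none
SiRe_2037	cold	early_stationary	-1.17	Oxidoreductase molybdopterin binding protein	down
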
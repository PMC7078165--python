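label	leafA	leafB	min	max
Chelicerata	Chelicerata_rep1	Chelicerata_rep2	509	538.8
Euchelicerata	Euchelicerata_rep1	Euchelicerata_rep2	500.5
Arachnopulmonata	Arachnopulmonata_rep1	Arachnopulmonata_rep2	432.6	509
Opiliones	Opiliones_rep1	Opiliones_rep2	405	509
Acari	Acari_rep1	Acari_rep2	405	509
Sarcoptiformes	Sarcoptiformes_rep1	Sarcoptiformes_rep2	382.7
Pedipalpi	Pedipalpi_rep1	Pedipalpi_rep2	319.9
Palpatores	Palpatores_rep1	Palpatores_rep2	298.75
Araneae	Araneae_rep1	Araneae_rep2	298.75
Avicularoidea	Avicularoidea_rep1	Avicularoidea_rep2	240.5
Xiphosurida	Xiphosurida_rep1	Xiphosurida_rep2	236
Synspermiata	Synspermiata_rep1	Synspermiata_rep2	158.1
Entelegynae	Entelegynae_rep1	Entelegynae_rep2	158.1
Araneoidea	Araneoidea_rep1	Araneoidea_rep2	129.41
Bipectina	Bipectina_rep1	Bipectina_rep2	125
Bothriuoidea_Scorpionoidea_Chactoidea	Bothriuoidea_Scorpionoidea_Chactoidea_rep1	Bothriuoidea_Scorpionoidea_Chactoidea_rep2	112.6
Cyphopthalmi	Cyphopthalmi_rep1	Cyphopthalmi_rep2	98.17
Laniatores	Laniatores_rep1	Laniatores_rep2	98.17
Metastriata	Metastriata_rep1	Metastriata_rep2	98.17
Buthida	Buthida_rep1	Buthida_rep2	48.5
Lobopodia	Lobopodia_rep1	Lobopodia_rep2	528.82	559
Altocrustacea	Altocrustacea_rep1	Altocrustacea_rep2	514
Progoneata	Progoneata_rep1	Progoneata_rep2	426.9
Chilopoda	Chilopoda_rep1	Chilopoda_rep2	416
Hexapoda	Hexapoda_rep1	Hexapoda_rep2	405
Aparaglossata	Aparaglossata_rep1	Aparaglossata_rep2	313.7
Onychophora	Onychophora_rep1	Onychophora_rep2	100
Mandibulata	Mandibulata_rep1	Mandibulata_rep2		538.8
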
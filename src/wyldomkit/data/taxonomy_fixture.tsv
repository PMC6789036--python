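sequence_id	species_id	superkingdom	phylum	class	order	family	genus
s01	spA	Bacteria	P1	P1_c	P1_o	P1_f	gA
s02	spA	Bacteria	P1	P1_c	P1_o	P1_f	gA
s03	spA	Bacteria	P1	P1_c	P1_o	P1_f	gA
s04	spB	Bacteria	P1	P1_c	P1_o	P1_f	gB
s05	spC	Bacteria	P2	P2_c	P2_o	P2_f	gC
s06	spC	Bacteria	P2	P2_c	P2_o	P2_f	gC
s07	spD	Bacteria	P3	P3_c	P3_o	P3_f	gD
s08	spD	Bacteria	P3	P3_c	P3_o	P3_f	gD
s09	spD	Bacteria	P3	P3_c	P3_o	P3_f	gD
s10	spD	Bacteria	P3	P3_c	P3_o	P3_f	gD
s11	spE	Bacteria	P3	P3_c	P3_o	P3_f	gE
s12	spF	Archaea	PA1	PA1_c	PA1_o	PA1_f	gF
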
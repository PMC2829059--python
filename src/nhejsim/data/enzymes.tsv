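# name	recognition	cut_top	cut_bottom
HindIII	AAGCTT	1	5
I-SceI	TAGGGATAACAGGGTAAT	9	5
BstXI	CCANNNNNNTGG	8	4
EcoRV	GATATC	3	3
AfeI	AGCGCT	3	3
Eco47III	AGCGCT	3	3
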
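# Genus-level summary of dimorphic-character counts as printed in the survey:
# per genus, number of species included / recognized, then mean, sample SD,
# min and max of the morphology, coloration, and total counts.  SD is blank
# for single-species genera (printed as a dash).
genus	n_included	n_total_in_genus	morph_mean	morph_sd	morph_min	morph_max	color_mean	color_sd	color_min	color_max	total_mean	total_sd	total_min	total_max
Acanthemblemaria	20	21	0.1	0.4	0	2	5.6	3.8	0	10	5.7	3.7	0	10
Chaenopsis	9	11	2.0	0.9	0	3	8.9	2.5	5	12	10.9	3.1	5	15
Cirriemblemaria	1	1	13		13	13	7		7	7	20		20	20
Coralliozetus	6	6	16.8	0.4	16	17	12.3	1.2	11	14	29.2	1.2	28	31
Ekemblemaria	2	3	1.0	0	1	1	5.5	0.7	5	6	6.5	0.7	6	7
Emblemaria	12	16	8.7	4.2	3	14	11.1	1.6	7	13	19.9	4.5	13	26
Emblemariopsis	7	14	3.4	2.1	0	6	9.9	1.6	7	12	13.3	3.2	9	17
Hemiemblemaria	1	1	0		0	0	0		0	0	0		0	0
Lucayablennius	1	1	0		0	0	3		3	3	3		3	3
Mccoskerichthys	1	1	1		1	1	0		0	0	1		1	1
Neoclinus	3	11	2.0	1.0	1	3	3.0	5.2	0	9	5.0	4.4	2	10
Protemblemaria	3	3	0.3	0.6	0	1	3.7	1.5	2	5	4.0	1.7	2	5
All genera	66	89	4.1	5.6	0	17	7.7	4.1	0	14	11.9	8.6	0	31
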
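# Per-species counts of sexually dimorphic characters by category, for the
# 66 chaenopsid species in the survey, with printed category totals.
# Category sizes: M-I 5, M-II 4, M-III 7, M-IV 6 (morphology 22);
# C-I 3, C-II 3, C-III 11 (coloration 17); grand total 39.
species	M-I	M-II	M-III	M-IV	M-Total	C-I	C-II	C-III	C-Total	Total
Acanthemblemaria aspera	0	0	0	0	0	2	2	6	10	10
Acanthemblemaria atrata	0	0	0	0	0	1	0	0	1	1
Acanthemblemaria balanorum	0	0	0	0	0	1	0	0	1	1
Acanthemblemaria betinensis	0	0	0	0	0	3	1	2	6	6
Acanthemblemaria castroi	0	0	0	0	0	2	1	3	6	6
Acanthemblemaria chaplini	0	0	0	0	0	3	2	5	10	10
Acanthemblemaria crockeri	0	0	0	0	0	2	2	3	7	7
Acanthemblemaria exilispinus	0	0	0	0	0	0	0	0	0	0
Acanthemblemaria greenfieldi	0	0	0	0	0	1	1	0	2	2
Acanthemblemaria hancocki	0	0	0	0	0	3	1	5	9	9
Acanthemblemaria harpeza	0	0	0	0	0	1	1	1	3	3
Acanthemblemaria hastingsi	0	0	0	0	0	3	2	5	10	10
Acanthemblemaria macrospilus	0	0	0	0	0	3	2	5	10	10
Acanthemblemaria mangognatha	0	0	0	0	0	2	0	1	3	3
Acanthemblemaria maria	0	0	0	0	0	0	0	0	0	0
Acanthemblemaria medusae	0	0	0	0	0	3	1	3	7	7
Acanthemblemaria paula	0	2	0	0	2	1	1	0	2	4
Acanthemblemaria rivasi	0	0	0	0	0	2	2	6	10	10
Acanthemblemaria spinosa	0	0	0	0	0	2	1	3	6	6
Acanthemblemaria stephensi	0	0	0	0	0	2	2	6	10	10
Chaenopsis alepidota	0	0	0	2	2	3	2	5	10	12
Chaenopsis coheni	0	0	0	2	2	3	2	6	11	13
Chaenopsis deltarrhis	0	0	0	2	2	3	1	6	10	12
Chaenopsis limbaughi	0	0	1	2	3	3	2	5	10	13
Chaenopsis ocellata	0	0	0	2	2	3	2	3	8	10
Chaenopsis resh	0	0	1	2	3	3	2	7	12	15
Chaenopsis roseola	0	0	0	0	0	2	0	3	5	5
Chaenopsis schmitti	0	0	0	2	2	3	0	6	9	11
Chaenopsis n_sp	0	0	0	2	2	2	0	3	5	7
Cirriemblemaria lucasana	3	3	3	4	13	1	0	6	7	20
Coralliozetus angelicus	5	4	3	5	17	3	2	8	13	30
Coralliozetus boehlkei	5	4	3	5	17	3	2	7	12	29
Coralliozetus cardonae	5	4	3	5	17	3	2	6	11	28
Coralliozetus micropes	5	4	3	5	17	3	2	9	14	31
Coralliozetus rosenblatti	5	3	3	5	16	3	2	8	13	29
Coralliozetus springeri	5	4	3	5	17	3	2	6	11	28
Ekemblemaria myersi	0	1	0	0	1	1	2	3	6	7
Ekemblemaria nigra	0	1	0	0	1	1	1	3	5	6
Emblemaria atlantica	3	4	1	4	12	3	2	6	11	23
Emblemaria caldwelli	0	1	0	4	5	3	2	6	11	16
Emblemaria caycedoi	0	1	1	2	4	3	1	5	9	13
Emblemaria diphyodontis	3	3	1	5	12	3	2	7	12	24
Emblemaria hudsoni	3	4	1	5	13	3	2	7	12	25
Emblemaria hyltoni	0	2	0	1	3	3	2	6	11	14
Emblemaria hypacanthus	3	4	1	6	14	3	2	7	12	26
Emblemaria nivipes	0	0	0	4	4	3	2	8	13	17
Emblemaria pandionis	0	1	0	4	5	3	2	7	12	17
Emblemaria piratica	3	3	1	5	12	3	2	7	12	24
Emblemaria piratula	2	2	0	5	9	3	2	7	12	21
Emblemaria walkeri	3	3	1	5	12	3	0	4	7	19
Emblemariopsis bahamensis	3	2	1	0	6	3	2	6	11	17
Emblemariopsis diaphana	1	1	0	0	2	3	2	5	10	12
Emblemariopsis leptocirris	1	2	0	0	3	3	2	5	10	13
Emblemariopsis occidentalis	2	2	1	0	5	3	2	5	10	15
Emblemariopsis pricei	0	0	0	0	0	3	1	5	9	9
Emblemariopsis randalli	1	1	1	0	3	1	1	5	7	10
Emblemariopsis signifera	2	1	1	1	5	3	2	7	12	17
Hemiemblemaria simulus	0	0	0	0	0	0	0	0	0	0
Lucayablennius zingaro	0	0	0	0	0	0	1	2	3	3
Mccoskerichthys sandae	0	1	0	0	1	0	0	0	0	1
Neoclinus blanchardi	0	1	0	1	2	0	0	0	0	2
Neoclinus stephensae	0	1	0	0	1	2	1	6	9	10
Neoclinus uninotatus	0	2	0	1	3	0	0	0	0	3
Protemblemaria bicirris	0	0	0	0	0	2	0	0	2	2
Protemblemaria perla	0	0	0	0	0	1	0	4	5	5
Protemblemaria punctata	0	0	0	1	1	2	0	2	4	5
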
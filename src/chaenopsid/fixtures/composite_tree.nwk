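(((Neoclinus_blanchardi,Neoclinus_stephensae,Neoclinus_uninotatus),Mccoskerichthys_sandae),((Coralliozetus_angelicus,Coralliozetus_boehlkei,Coralliozetus_cardonae,Coralliozetus_micropes,Coralliozetus_rosenblatti,Coralliozetus_springeri),(((Protemblemaria_bicirris,Protemblemaria_perla,Protemblemaria_punctata),Cirriemblemaria_lucasana,(Emblemariopsis_bahamensis,Emblemariopsis_diaphana,Emblemariopsis_leptocirris,Emblemariopsis_occidentalis,Emblemariopsis_pricei,Emblemariopsis_randalli,Emblemariopsis_signifera)),((Acanthemblemaria_aspera,Acanthemblemaria_atrata,Acanthemblemaria_balanorum,Acanthemblemaria_betinensis,Acanthemblemaria_castroi,Acanthemblemaria_chaplini,Acanthemblemaria_crockeri,Acanthemblemaria_exilispinus,Acanthemblemaria_greenfieldi,Acanthemblemaria_hancocki,Acanthemblemaria_harpeza,Acanthemblemaria_hastingsi,Acanthemblemaria_macrospilus,Acanthemblemaria_mangognatha,Acanthemblemaria_maria,Acanthemblemaria_medusae,Acanthemblemaria_paula,Acanthemblemaria_rivasi,Acanthemblemaria_spinosa,Acanthemblemaria_stephensi),(((Ekemblemaria_myersi,Ekemblemaria_nigra),Hemiemblemaria_simulus),(Lucayablennius_zingaro,(Chaenopsis_alepidota,Chaenopsis_coheni,Chaenopsis_deltarrhis,Chaenopsis_limbaughi,'Chaenopsis n_sp',Chaenopsis_ocellata,Chaenopsis_resh,Chaenopsis_roseola,Chaenopsis_schmitti),((Emblemaria_caldwelli,Emblemaria_caycedoi,Emblemaria_hyltoni),Emblemaria_atlantica,Emblemaria_diphyodontis,Emblemaria_hudsoni,Emblemaria_hypacanthus,Emblemaria_nivipes,Emblemaria_pandionis,Emblemaria_piratica,Emblemaria_piratula,Emblemaria_walkeri)))))));
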
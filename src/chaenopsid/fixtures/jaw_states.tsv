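# SYNTHETIC / BEST-EFFORT reconstruction of per-species jaw-length states
# (character M-IIb: posterior extent of the maxilla tip) for males and
# females.  The survey's raw per-species scores are in its supplementary
# material, which is not packaged here; this table encodes the states the
# running text pins down (ancestral dimorphism with long-jawed males and
# short-jawed females; male elongation in Neoclinus blanchardi and
# N. uninotatus; female elongation to monomorphism in N. stephensae,
# Protemblemaria, and Acanthemblemaria; shared elongation in most Chaenopsis;
# shared reduction in Lucayablennius zingaro; female reduction within
# Emblemaria; pedomorphic short-jawed females throughout Coralliozetus) and
# fills the remaining species with choices consistent with the per-species
# dimorphism counts.  Treat it as illustrative, not authoritative.
species	sex	char_id	state
Neoclinus blanchardi	male	M-IIb	past-opercle
Neoclinus blanchardi	female	M-IIb	to-orbit-margin
Neoclinus stephensae	male	M-IIb	past-orbit
Neoclinus stephensae	female	M-IIb	past-orbit
Neoclinus uninotatus	male	M-IIb	past-preopercle
Neoclinus uninotatus	female	M-IIb	short-of-orbit
Mccoskerichthys sandae	male	M-IIb	past-orbit
Mccoskerichthys sandae	female	M-IIb	short-of-orbit
Coralliozetus angelicus	male	M-IIb	past-preopercle
Coralliozetus angelicus	female	M-IIb	to-orbit-margin
Coralliozetus boehlkei	male	M-IIb	past-preopercle
Coralliozetus boehlkei	female	M-IIb	short-of-orbit
Coralliozetus cardonae	male	M-IIb	past-preopercle
Coralliozetus cardonae	female	M-IIb	short-of-orbit
Coralliozetus micropes	male	M-IIb	past-preopercle
Coralliozetus micropes	female	M-IIb	short-of-orbit
Coralliozetus rosenblatti	male	M-IIb	past-preopercle
Coralliozetus rosenblatti	female	M-IIb	short-of-orbit
Coralliozetus springeri	male	M-IIb	past-preopercle
Coralliozetus springeri	female	M-IIb	short-of-orbit
Protemblemaria bicirris	male	M-IIb	past-orbit
Protemblemaria bicirris	female	M-IIb	past-orbit
Protemblemaria perla	male	M-IIb	past-orbit
Protemblemaria perla	female	M-IIb	past-orbit
Protemblemaria punctata	male	M-IIb	past-orbit
Protemblemaria punctata	female	M-IIb	past-orbit
Cirriemblemaria lucasana	male	M-IIb	past-preopercle
Cirriemblemaria lucasana	female	M-IIb	short-of-orbit
Emblemariopsis bahamensis	male	M-IIb	past-orbit
Emblemariopsis bahamensis	female	M-IIb	past-orbit
Emblemariopsis diaphana	male	M-IIb	past-orbit
Emblemariopsis diaphana	female	M-IIb	past-orbit
Emblemariopsis leptocirris	male	M-IIb	past-orbit
Emblemariopsis leptocirris	female	M-IIb	past-orbit
Emblemariopsis occidentalis	male	M-IIb	past-orbit
Emblemariopsis occidentalis	female	M-IIb	past-orbit
Emblemariopsis pricei	male	M-IIb	past-orbit
Emblemariopsis pricei	female	M-IIb	past-orbit
Emblemariopsis randalli	male	M-IIb	past-orbit
Emblemariopsis randalli	female	M-IIb	past-orbit
Emblemariopsis signifera	male	M-IIb	past-orbit
Emblemariopsis signifera	female	M-IIb	past-orbit
Acanthemblemaria aspera	male	M-IIb	past-orbit
Acanthemblemaria aspera	female	M-IIb	past-orbit
Acanthemblemaria atrata	male	M-IIb	past-orbit
Acanthemblemaria atrata	female	M-IIb	past-orbit
Acanthemblemaria balanorum	male	M-IIb	past-orbit
Acanthemblemaria balanorum	female	M-IIb	past-orbit
Acanthemblemaria betinensis	male	M-IIb	past-orbit
Acanthemblemaria betinensis	female	M-IIb	past-orbit
Acanthemblemaria castroi	male	M-IIb	past-orbit
Acanthemblemaria castroi	female	M-IIb	past-orbit
Acanthemblemaria chaplini	male	M-IIb	past-orbit
Acanthemblemaria chaplini	female	M-IIb	past-orbit
Acanthemblemaria crockeri	male	M-IIb	past-orbit
Acanthemblemaria crockeri	female	M-IIb	past-orbit
Acanthemblemaria exilispinus	male	M-IIb	past-orbit
Acanthemblemaria exilispinus	female	M-IIb	past-orbit
Acanthemblemaria greenfieldi	male	M-IIb	past-orbit
Acanthemblemaria greenfieldi	female	M-IIb	past-orbit
Acanthemblemaria hancocki	male	M-IIb	past-orbit
Acanthemblemaria hancocki	female	M-IIb	past-orbit
Acanthemblemaria harpeza	male	M-IIb	past-orbit
Acanthemblemaria harpeza	female	M-IIb	past-orbit
Acanthemblemaria hastingsi	male	M-IIb	past-orbit
Acanthemblemaria hastingsi	female	M-IIb	past-orbit
Acanthemblemaria macrospilus	male	M-IIb	past-orbit
Acanthemblemaria macrospilus	female	M-IIb	past-orbit
Acanthemblemaria mangognatha	male	M-IIb	past-orbit
Acanthemblemaria mangognatha	female	M-IIb	past-orbit
Acanthemblemaria maria	male	M-IIb	past-orbit
Acanthemblemaria maria	female	M-IIb	past-orbit
Acanthemblemaria medusae	male	M-IIb	past-orbit
Acanthemblemaria medusae	female	M-IIb	past-orbit
Acanthemblemaria paula	male	M-IIb	past-orbit
Acanthemblemaria paula	female	M-IIb	past-orbit
Acanthemblemaria rivasi	male	M-IIb	past-orbit
Acanthemblemaria rivasi	female	M-IIb	past-orbit
Acanthemblemaria spinosa	male	M-IIb	past-orbit
Acanthemblemaria spinosa	female	M-IIb	past-orbit
Acanthemblemaria stephensi	male	M-IIb	past-orbit
Acanthemblemaria stephensi	female	M-IIb	past-orbit
Ekemblemaria myersi	male	M-IIb	past-orbit
Ekemblemaria myersi	female	M-IIb	past-orbit
Ekemblemaria nigra	male	M-IIb	past-orbit
Ekemblemaria nigra	female	M-IIb	past-orbit
Hemiemblemaria simulus	male	M-IIb	to-orbit-margin
Hemiemblemaria simulus	female	M-IIb	to-orbit-margin
Lucayablennius zingaro	male	M-IIb	short-of-orbit
Lucayablennius zingaro	female	M-IIb	short-of-orbit
Chaenopsis alepidota	male	M-IIb	past-preopercle
Chaenopsis alepidota	female	M-IIb	past-preopercle
Chaenopsis coheni	male	M-IIb	past-preopercle
Chaenopsis coheni	female	M-IIb	past-preopercle
Chaenopsis deltarrhis	male	M-IIb	past-preopercle
Chaenopsis deltarrhis	female	M-IIb	past-preopercle
Chaenopsis limbaughi	male	M-IIb	past-preopercle
Chaenopsis limbaughi	female	M-IIb	past-preopercle
Chaenopsis ocellata	male	M-IIb	past-preopercle
Chaenopsis ocellata	female	M-IIb	past-preopercle
Chaenopsis resh	male	M-IIb	past-preopercle
Chaenopsis resh	female	M-IIb	past-preopercle
Chaenopsis roseola	male	M-IIb	past-orbit
Chaenopsis roseola	female	M-IIb	past-orbit
Chaenopsis schmitti	male	M-IIb	past-preopercle
Chaenopsis schmitti	female	M-IIb	past-preopercle
Chaenopsis n_sp	male	M-IIb	past-orbit
Chaenopsis n_sp	female	M-IIb	past-orbit
Emblemaria atlantica	male	M-IIb	past-orbit
Emblemaria atlantica	female	M-IIb	short-of-orbit
Emblemaria caldwelli	male	M-IIb	past-orbit
Emblemaria caldwelli	female	M-IIb	past-orbit
Emblemaria caycedoi	male	M-IIb	past-orbit
Emblemaria caycedoi	female	M-IIb	past-orbit
Emblemaria diphyodontis	male	M-IIb	past-orbit
Emblemaria diphyodontis	female	M-IIb	short-of-orbit
Emblemaria hudsoni	male	M-IIb	past-orbit
Emblemaria hudsoni	female	M-IIb	short-of-orbit
Emblemaria hyltoni	male	M-IIb	past-orbit
Emblemaria hyltoni	female	M-IIb	past-orbit
Emblemaria hypacanthus	male	M-IIb	past-orbit
Emblemaria hypacanthus	female	M-IIb	short-of-orbit
Emblemaria nivipes	male	M-IIb	past-orbit
Emblemaria nivipes	female	M-IIb	past-orbit
Emblemaria pandionis	male	M-IIb	past-orbit
Emblemaria pandionis	female	M-IIb	short-of-orbit
Emblemaria piratica	male	M-IIb	past-orbit
Emblemaria piratica	female	M-IIb	short-of-orbit
Emblemaria piratula	male	M-IIb	past-orbit
Emblemaria piratula	female	M-IIb	to-orbit-margin
Emblemaria walkeri	male	M-IIb	past-orbit
Emblemaria walkeri	female	M-IIb	to-orbit-margin
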
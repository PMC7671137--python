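# Catalogue of the 39 discrete sexually dimorphic characters surveyed across
# chaenopsid blennies: 22 morphology (M-I osteology, M-II morphometrics,
# M-III soft anatomy, M-IV fins) and 17 melanophore coloration (C-I head,
# C-II body, C-III fins).  State labels are unordered for mapping.
char_id	category	description	states
M-Ia	M-I	Robustness of the infraorbital bones	slender|thick
M-Ib	M-I	Number of infraorbital elements	two|three|four
M-Ic	M-I	Surface texture of the infraorbital bones	smooth|pits|spines|ridges
M-Id	M-I	Fusion of the nasal bones	fused|separate
M-Ie	M-I	Surface texture of the nasal bones	smooth|pits|spines|ridges|knobs
M-IIa	M-II	Head profile shape	rounded|pointed|elongate
M-IIb	M-II	Posterior extent of the jaw (maxilla tip) relative to head landmarks	short-of-orbit|to-orbit-margin|past-orbit|past-preopercle|past-opercle
M-IIc	M-II	Length of the supraorbital cirrus	absent|short|moderate|long
M-IId	M-II	Length of the nasal cirrus	absent|tiny|short|long
M-IIIa	M-III	Shape of the lips	flat|protruding
M-IIIb	M-III	Dewlap on the chin	absent|present
M-IIIc	M-III	Fleshy flaps on the snout	absent|present
M-IIId	M-III	Papillae on the nape	absent|present
M-IIIe	M-III	Fleshy folds on the nape	absent|present
M-IIIf	M-III	Muscles over the nape	absent|present
M-IIIg	M-III	Number of dorsal sensory pores	few|moderate|many
M-IVa	M-IV	Shape of the anterior dorsal fin	low|elevated|sail-like|spike-like
M-IVb	M-IV	Overall size of the dorsal fin	small|moderate|large
M-IVc	M-IV	Flap on the anterior dorsal fin	absent|thin|moderate|flaglike
M-IVd	M-IV	Notch in the dorsal-fin margin	absent|slight|deep
M-IVe	M-IV	Shape of the pectoral fin	rounded|pointed
M-IVf	M-IV	Incision of pelvic-fin membranes between segmented rays	incised|not-incised
C-Ia	C-I	Overall melanophore density on the head	light|moderate|dark
C-Ib	C-I	Melanophore pattern on the lower jaw	uniform-light|uniform-dark|banded
C-Ic	C-I	Melanophore density on the branchiostegal membranes	light|moderate|dark
C-IIa	C-II	Melanophore density on the lateral body	light|moderate|dark
C-IIb	C-II	Melanophore density on the abdomen	light|moderate|dark
C-IIc	C-II	Pigmentation anterior to the pelvic fins	dark|clear-areas
C-IIIa	C-III	Melanophore density on the anterior dorsal fin	light|moderate|dark
C-IIIb	C-III	Dorsal-fin spot or spots	absent|present
C-IIIc	C-III	Melanophore density on the posterior dorsal fin	light|moderate|dark
C-IIId	C-III	Clear windows in the dorsal fin	absent|present
C-IIIe	C-III	Melanophore density on the caudal fin	light|moderate|dark
C-IIIf	C-III	Melanophore density on the anal fin	light|moderate|dark
C-IIIg	C-III	Clear areas in the posterior median fins	dark|clear-areas
C-IIIh	C-III	Melanophore density on the pectoral-fin base	light|moderate|dark
C-IIIi	C-III	Melanophore density on the pectoral fin	light|moderate|dark
C-IIIj	C-III	Bands on the pectoral fin	absent|present
C-IIIk	C-III	Melanophore density on the pelvic fin	light|moderate|dark
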
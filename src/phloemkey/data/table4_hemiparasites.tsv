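genus	life_form	vein_subtype
Bartsia	perennial_herb	1-I
Castilleja	annual_herb	1-II
Pedicularis	perennial_herb	1-II
Euphrasia	annual_herb	2-VI
Melampyrum	annual_herb	2-VI
Odontites	annual_herb	2-VI
Rhinanthus	annual_herb	2-VI
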
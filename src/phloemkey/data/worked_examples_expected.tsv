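taxon	cc_labels	cc_ambiguous	vein_label
Swertia obtusa	OC-a		0
Vinca minor	OC-b		
Onosma gmelinii	TC-a		
Dracocephalum peregrinum	IC;TC-b		1-III
Gentiana aquatica	TC-c		2-V
Hamelia patens		IC;ICL	
Catesbaea spinosa	ICL		
Amsonia tabernaemontana	CC-b		1-IV
Asarina barclaiana	MIC-a		
Rhinanthus minor	MIC-b		2-VI
Scutellaria pallida	IC		1-I
Mimulus guttatus	IC;OC-a		1-II
Trachelospermum luikinense	OC-b		0
Ehretia cordifolia	OC-b		2-I
Veronica chamaedrys	OC-b		2-II
Galium krylovianum	TC-a		2-III
Aster alpinus	TC-a		2-IV
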
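# Microtubule-attachment interactions for the attached kinetochore variants.
# These pairs are fixture choices of the bundled model (synthetic; the source
# interaction table lists no microtubule partners): the Ndc80 complex binds
# the microtubule lattice through Hec1, the Ska complex binds both the
# microtubule and the Ndc80 complex.
protein_A	protein_B	site_A	site_B	rate_tag	switch
Hec1	Tubulin	tubulin	hec1	kon
Ska1	Tubulin	tubulin	ska1	kon
Ska3	Hec1	hec1	ska3	kon
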
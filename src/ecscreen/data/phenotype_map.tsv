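# Explicit gene-to-phenotype mapping used by triage in addition to
# disease-name token overlap (clinician-style synonym knowledge).
symbol	phenotype
GJB2	deafness
GJB2	hearing impairment
GJB2	surdimutism
HBB	anemia
HBB	thalassemia
USH2A	hearing impairment
USH2A	retinitis pigmentosa
PAX6	aniridia
PAX6	nystagmus
DMD	muscular dystrophy
DUOX2	hypothyroidism
GALC	intellectual disability
CACNA1F	night blindness
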
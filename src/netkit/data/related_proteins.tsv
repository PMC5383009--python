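# 13 proteins related to amyloid fibril formation
# (10 in vitro amyloid-forming precursors + 3 amyloid-related proteins)
# name	abbreviation	accession	category
alpha beta Crystallin	HspB5	P02511	in_vitro_amyloid
alpha-Synuclein	NACP	P37840	in_vitro_amyloid
Apolipoprotein C-II	Apo-CII	P02655	in_vitro_amyloid
Caspase-3 precursor	CASP-3	P42574	in_vitro_amyloid
Cystic fibrosis transmembrane conductance regulator	CFTR	P13569	in_vitro_amyloid
Huntingtin	HD	P42858	in_vitro_amyloid
Presenilin 1	PS-1	P49768	in_vitro_amyloid
Presenilin 2	PS-2	P49810	in_vitro_amyloid
Spectrin SH3	Spectrin	Q13813	in_vitro_amyloid
Tau	Tau	P10636	in_vitro_amyloid
Actin, cytoplasmic 1	Actin	P60709	amyloid_related
Apolipoprotein E	Apo-E	P02649	amyloid_related
Ataxin 1	Ataxin-1	P54253	amyloid_related
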
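# 28 in vivo amyloid-forming precursor proteins (seed dataset)
# name	abbreviation	accession	category
Amyloid beta A4 protein	Abeta	P05067	in_vivo_amyloid
Apolipoprotein A-I	AApoAI	P02647	in_vivo_amyloid
Apolipoprotein A-II	AApoAII	P02652	in_vivo_amyloid
Apolipoprotein A-IV	AApoAIV	P06727	in_vivo_amyloid
Beta-2-microglobulin	Abeta2M	P61769	in_vivo_amyloid
Calcitonin	ACal	P01258	in_vivo_amyloid
Corneodesmosin	ACor	Q15517	in_vivo_amyloid
Cystatin-C	ACys	P01034	in_vivo_amyloid
Fibrinogen alpha chain	Afib	P02671	in_vivo_amyloid
Galectin 7	AGal	P47929	in_vivo_amyloid
Gelsolin	AGel	P06396	in_vivo_amyloid
Insulin	AIns	P01308	in_vivo_amyloid
Integral membrane protein 2B	ABri/ADan	Q9Y287	in_vivo_amyloid
Islet Amyloid Polypeptide	AIAPP	P10997	in_vivo_amyloid
Kerato-epithelin	AKer	Q15582	in_vivo_amyloid
Lactadherin	AMed	Q08431	in_vivo_amyloid
Lactoferrin	ALac	P02788	in_vivo_amyloid
Leukocyte cell-derived chemotaxin-2	ALECT2	O14960	in_vivo_amyloid
Lysozyme C	ALys	P61626	in_vivo_amyloid
Major prion protein	APrP	P04156	in_vivo_amyloid
Natriuretic peptides A	AANF	P01160	in_vivo_amyloid
Odontogenic Ameloblast-Associated Protein	AOAAP	A1E959	in_vivo_amyloid
Prolactin	APro	P01236	in_vivo_amyloid
Pulmonary surfactant associated protein C	APSP	P11686	in_vivo_amyloid
Semenogelin-1	ASem1	P04279	in_vivo_amyloid
Serum amyloid A-1	AA1	P0DJI8	in_vivo_amyloid
Serum amyloid A-2	AA2	P0DJI9	in_vivo_amyloid
Transthyretin	ATTR	P02766	in_vivo_amyloid
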
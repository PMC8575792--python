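set_name	K	description	k	ratio	p	q	overlap_genes
HP_GONOSOMAL_INHERITANCE	253	Gonosomal inheritance	12	0.0474	1.49E-20	6.70E-17	ATRX,OCRL,THOC2,MAOA,KIF4A,BCORL1,XIAP,POF1B,PHKA1,BCOR,AMER1,UBQLN2
HP_X_LINKED_RECESSIVE_INHERITANCE	173	X-linked recessive inheritance	9	0.052	8.13E-16	1.83E-12	ATRX,OCRL,THOC2,MAOA,KIF4A,BCORL1,XIAP,POF1B,PHKA1
HP_SELF_INJURIOUS_BEHAVIOR	108	Self-injurious behaviour	6	0.0556	5.66E-11	8.47E-08	ATRX,OCRL,THOC2,MAOA,BCOR,ELP2
HP_ABNORMAL_EMOTION_AFFECT_BEHAVIOR	415	Abnormal emotion/affect behaviour	7	0.0169	4.97E-09	4.97E-06	ATRX,OCRL,THOC2,MAOA,BCOR,ELP2,VPS13C
HP_NEUROLOGICAL_SPEECH_IMPAIRMENT	1022	Neurological speech impairment	9	0.0088	6.24E-09	4.97E-06	ATRX,OCRL,KIF4A,BCOR,AMER1,UBQLN2,ELP2,ZNF41,HACE1
HP_DELAYED_SPEECH_AND_LANGUAGE_DEVELOPMENT	696	Delayed speech and language development	8	0.0115	6.63E-09	4.97E-06	ATRX,THOC2,BCORL1,AMER1,ELP2,ZNF41,HACE1,CEP63
HP_AUTISTIC_BEHAVIOR	450	Autistic behaviour	7	0.0156	8.68E-09	5.12E-06	ATRX,THOC2,MAOA,BCORL1,BCOR,VPS13C,ZNF41
HP_ABNORMAL_AGGRESSIVE_IMPULSIVE_OR_VIOLENT_BEHAVIOR	251	Abnormal aggressive, impulsive or violent behaviour	6	0.0239	9.12E-09	5.12E-06	ATRX,OCRL,THOC2,MAOA,BCOR,ELP2
HP_SHORT_STATURE	1152	Short stature	9	0.0078	1.75E-08	8.76E-06	ATRX,OCRL,THOC2,BCOR,AMER1,ELP2,HACE1,CEP63,INVS
HP_INVOLUNTARY_MOVEMENTS	905	Involuntary movements	8	0.0088	5.05E-08	2.19E-05	ATRX,OCRL,THOC2,MAOA,BCORL1,UBQLN2,ELP2,VPS13C
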
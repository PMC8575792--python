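proband	proband_sex	chrom	pos	ref	alt	gene	moi	gt_proband
BA003	F
BA005	M
BA009	M	chrX	130015441	G	A	BCORL1	X-linked	HEMI_ALT
BA016	M	chrX	56565305	C	G	UBQLN2	X-linked	HEMI_ALT
BA021	F
BA023	M
BA025	F
BA030	M
BA031	M
BA032	M	chr2	173016403	C	A	RAPGEF4	AR	HOM_ALT
BA032	M	chrX	129590191	T	A	OCRL	X-linked	HEMI_ALT
BA035	F
BA036	F	chr16	75243074	G	A	BCAR1	De novo	HET
BA037	M	chr9	20948857	C	A	FOCAD	AR	HOM_ALT
BA037	M	chrX	70341839	A	C	KIF4A	X-linked	HEMI_ALT
BA038	M	chrX	47448875	G	A	ZNF41	X-linked	HEMI_ALT
BA039	F
BA040	M	chrX	3112294	C	T	ARSF	X-linked	HEMI_ALT
BA040	M	chrX	64191164	G	T	AMER1	X-linked	HEMI_ALT
BA041	M	chr9	100126394	C	G	INVS	AR	HOM_ALT
BA041	M	chrX	129557351	G	C	OCRL	X-linked	HEMI_ALT
BA0XX	0
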
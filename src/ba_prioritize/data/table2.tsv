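proband	proband_sex	chrom	pos	ref	alt	gene	transcript_change	consequence	moi_printed	gt_proband	gt_mother	gt_father	gt_sib	maf_khv	maf_gnomad_eas	maf_1kg	cadd_phred
BA002_4	M	chr6	104771988	G	A	HACE1	NM_001350555:c.G1660>A	missense	AR	HOM_ALT	HET	HET	HET	0.01	0.001731	0.001996	26.2
BA002_4	M	chrX	72684557	G	A	PHKA1	NM_001122670:c.G478>A	missense	X-linked	HEMI_ALT	HET	HEMI_REF	HET	0.008	0.001949	0.005298	23.2
BA002_4	M	chrX	123665767	G	A	THOC2	NM_001081550:c.G1261>A	missense	X-linked	HEMI_ALT	HET	HEMI_REF	HET	0.008	0.01483	0.01589	21.6
BA004	M	chrX	123888703	C	G	XIAP	NM_001167:c.C962>G	missense	X-linked	HEMI_ALT	HET	MISSING		0	0.003356	0.003958	29.5
BA007	M	chr15	61929659	C	G	VPS13C	NM_017684:c.C5999>G	missense	AR	HOM_ALT	HET	HET		0.01	0.005391	0.00998	24.3
BA007	M	chrX	64192212	A	T	AMER1	NM_152424:c.A1075>T	missense	X-linked	HEMI_ALT	HET	HEMI_REF		0	0.0002802	0	25
BA007	M	chrX	77508398	C	G	ATRX	NM_138270:c.C7318>G	missense	X-linked	HEMI_ALT	HET	HEMI_REF		0	0.0005613	0.001323	22.3
BA007	M	chrX	85367724	A	C	POF1B	NM_001307940:c.A325>C	missense	X-linked	HEMI_ALT	HET	HEMI_REF		0.003	0.001392	0.001321	19.47
BA009	M	chrX	130015441	G	A	BCORL1	NM_001184772:c.G2669>A	missense	X-linked	HEMI_ALT	HET	HEMI_REF		0.008	0.001949	0.002635	23.3
BA014	F	chr9	100252390	C	T	INVS	NM_001318382:c.C208>T	stopgain	De novo	HET	HOM_REF	MISSING		0	0	0	37
BA014	F	chrX	40073898	G	A	BCOR	NM_001123383:c.C1448>T	missense	X-linked	HOM_ALT	HET	MISSING		0.003	0.003068	0.001321	23.1
BA016	M	chrX	56565305	C	G	UBQLN2	NM_013444:c.C1432>G	missense	X-linked	HEMI_ALT	HET	HEMI_REF		0	0	0	23.7
BA020	M	chrX	43693330	G	A	MAOA	NM_000240:c.G208>A	missense	X-linked	HEMI_ALT	HET	HEMI_REF		0	0	0	22.6
BA020	M	chrX	108733510	G	C	IRS4	NM_003604:c.G2835>C	missense	X-linked	HEMI_ALT	HET	HEMI_REF		0.003	0	0	22.8
BA028	M	chr18	36156524	C	T	ELP2	NM_001242879:c.C1124>T	missense	De novo	HET	HOM_REF	HOM_REF		0	0	0	26.3
BA032	M	chr2	173016403	C	A	RAPGEF4	NM_001282901:c.C1204>A	missense	AR	HOM_ALT	HET	HET		0	0.0001925	0	23.2
BA032	M	chrX	129590191	T	A	OCRL	NM_001587:c.T2603>A	missense	X-linked	HEMI_ALT	HET	HEMI_REF		0.003	0	0	18.03
BA033	F	chr6	54308777	C	T	TINAG	NM_014464:c.C227>T	missense	De novo	HET	HOM_REF	HOM_REF		0	0	0	22.2
BA035	F	chr3	134561515	C	A	CEP63	NM_001042383:c.C1468>A	missense	De novo	HET	HOM_REF	HOM_REF		0	0	0	23.5
BA035	F	chr7	128812751	C	A	CCDC136	NM_022742:c.C2585>A	missense	De novo	HET	HOM_REF	HOM_REF		0	0	0	14.62
BA036	F	chr16	75243074	G	A	BCAR1	NM_001170715:c.C83>T	missense	De novo	HET	HOM_REF	HOM_REF		0	0	0	29.4
BA037	M	chr9	20948857	C	A	FOCAD	NM_017794:c.C3805>A	missense	AR	HOM_ALT	HET	HET		0.005	0.0005763	0.001996	23.2
BA037	M	chrX	70341839	A	C	KIF4A	NM_012310:c.A1174>C	missense	X-linked	HEMI_ALT	HET	HEMI_REF		0	0.005278	0.001379	25.1
BA038	M	chrX	47448875	G	A	ZNF41	NM_001324139:c.C637>T	missense	X-linked	HEMI_ALT	HET	HEMI_REF		0.003	0	0	15.37
BA040	M	chrX	3112294	C	T	ARSF	NM_001201538:c.C1511>T	missense	X-linked	HEMI_ALT	HET	HEMI_REF		0.003	0	0	22.8
BA040	M	chrX	64191164	G	T	AMER1	NM_152424:c.C2123>A	missense	X-linked	HEMI_ALT	HET	HEMI_REF		0.003	0	0	14.16
BA041	M	chr9	100126394	C	G	INVS	NM_014425:c.C118>G	missense	AR	HOM_ALT	HET	HET		0.007	0.004996	0.005988	22.7
BA041	M	chrX	129557351	G	C	OCRL	NM_000276:c.G265>C	missense	X-linked	HEMI_ALT	HET	HEMI_REF		0.007	0.0008396	0.002639	24.1
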
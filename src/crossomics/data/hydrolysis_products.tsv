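species	parent_glucosinolate	compound	product_class	mean	sd
NZ	S-2OH3-butenyl	goitrin	isothiocyanate	1394	698
NZ	S-2OH3-butenyl	2OH3but-CN	nitrile/epithionitrile	590	100
NZ	S-2OH3-butenyl	epithio-2OH3B-I	nitrile/epithionitrile	2446	397
NZ	S-2OH3-butenyl	epithio-2OH3B-II	nitrile/epithionitrile	2269	371
NZ	allyl	allyl-ITC	isothiocyanate	1622	668
NZ	allyl	epithio-allyl	nitrile/epithionitrile	1868	450
NZ	3-butenyl	3-but-ITC	isothiocyanate	162	45
NZ	3MTP	3MTP-ITC	isothiocyanate	449	226
NZ	3MTP	3MTP-CN	nitrile/epithionitrile	67	27
NZ	3MSOP	3MSOP-ITC	isothiocyanate	30	41
NZ	4MTB	4MTB-ITC	isothiocyanate	210	122
NZ	4MTB	4MTB-CN	nitrile/epithionitrile	22	14
NZ	4MSOB	4MSOB-ITC	isothiocyanate	58	48
NZ	8MTO	8MTO-ITC	isothiocyanate	27	9
NZ	9MTN	9MTN-ITC	isothiocyanate	28	6
CH	S-2OH3-butenyl	goitrin	isothiocyanate	5115	981
CH	S-2OH3-butenyl	2OH3but-CN	nitrile/epithionitrile	32	15
CH	allyl	allyl-ITC	isothiocyanate	3261	997
CH	allyl	epithio-allyl	nitrile/epithionitrile	4	2
CH	3-butenyl	3-but-ITC	isothiocyanate	9	4
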
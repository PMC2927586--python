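po_code	po_name	n_promoters
PO:0000036	Leaf vascular system	38
PO:0009005	root	37
PO:0005660	hydathode	35
PO:0000013	cauline leaf	32
PO:0003011	root vascular system	32
PO:0000056	floral bud	26
PO:0006504	leaf trichome	25
PO:0009052	pedicel	24
PO:0009032	petal	22
PO:0006502	flower abscission zone	21
PO:0006325	inflorescence node	20
PO:0000282	trichome	20
PO:0009031	sepal	19
PO:0000054	petal vascular system	17
PO:0009001	fruit	14
PO:0020139	midvein	14
PO:0000293	guard cell	12
PO:0009049	inflorescence	12
PO:0009047	stem	12
PO:0006056	cotyledon epidermis	11
PO:0006016	leaf epidermis	11
PO:0000112	stem epidermis	11
PO:0000115	socket cell	10
PO:0000146	abscission zone	9
PO:0004707	fruit dehiscence zone	9
PO:0009010	seed	9
PO:0004723	sepal vascular system	9
PO:0009067	filament	8
PO:0020127	primary root	8
PO:0006040	sepal epidermis	8
PO:0000039	stem vascular system	8
PO:0000034	vascular system	8
PO:0006501	leaf abscission zone	7
PO:0020128	leaf margin	7
PO:0000332	pavement cell	7
PO:0005003	stem trichome	7
PO:0000035	cotyledon vascular system	6
PO:0005679	epidermis	6
PO:0009025	leaf	6
PO:0006036	root epidermis	6
PO:0009030	carpel	5
PO:0000025	root tip	5
PO:0009015	vascular tissue	5
PO:0020030	cotyledon	4
PO:0004536	fruit pedicel	4
PO:0009072	ovary	4
PO:0000052	petiole vascular system	4
PO:0000256	root hair	4
PO:0009046	flower	3
PO:0004724	hypocotyl-root junction	3
PO:0009081	inflorescence branch	3
PO:0005028	inflorescence vascular system	3
PO:0005645	leaf mesophyll	3
PO:0009053	peduncle	3
PO:0005021	sepal margin	3
PO:0000033	valve	3
PO:0005011	anther dehiscence zone	2
PO:0005008	fruit septum	2
PO:0008003	fruit vascular system	2
PO:0020100	hypocotyl	2
PO:0006019	leaf abaxial epidermis	2
PO:0004006	mesophyll cell	2
PO:0000051	petiole epidermis	2
PO:0020031	radicle	2
PO:0020141	stem node	2
PO:0004711	axillary inflorescence bud	1
PO:0005019	carpel vascular system	1
PO:0006338	embryonic leaf	1
PO:0008015	hypocotyl vascular system	1
PO:0006339	juvenile leaf	1
PO:0020121	lateral root	1
PO:0000017	leaf primordium	1
PO:0006034	leaflet margin	1
PO:0020091	male gametophyte	1
PO:0005012	pedicel vascular system	1
PO:0006041	petal epidermis	1
PO:0006081	primary root apical meristem	1
PO:0006085	root meristem	1
PO:0000014	rosette leaf	1
PO:0009073	stigma	1
PO:0020041	stipule	1
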
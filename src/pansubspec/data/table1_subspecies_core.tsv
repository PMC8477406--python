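subspecies	core_gene_id	prevalence_pct	hgt_status
longum	B1_0665	99	Native
longum	B1_0666	98	Native
longum	B1_1343	98	Native
longum	B1_0094	98	Native
longum	B1_0106	98	Native
longum	B1_0884	98	Native
longum	B1_1277	97	Native
longum	B1_0628	97	Native
longum	B1_0345	97	Native
longum	B1_1278	97	Native
longum	B1_0156	95	Native
longum	B1_1275	95	Native
longum	B1_0738	94	Native
longum	B1_1795	93	Native
longum	B1_0431	91	Native
longum	B1_1294	90	Native
longum	B1_0735	90	Foreign
longum	B1_0883	90	Native
longum	B1_0737	89	Foreign
longum	134B_0607	88	Native
longum	134B_0472	88	Native
longum	B1_1296	88	Native
longum	B1_0107	86	Native
longum	B1_0786	86	Native
infantis	ACJ51545.1	100	Native
infantis	ACJ53225.1	100	Native
infantis	ACJ52470.1	100	Native
infantis	ACJ52099.1	100	Foreign
infantis	ACJ51227.1	100	Native
infantis	ACJ52098.1	100	Native
infantis	ACJ53071.1	100	Native
infantis	ACJ51238.1	100	Native
infantis	ACJ51551.1	100	Foreign
infantis	ACJ51549.1	100	Native
infantis	ACJ53072.1	100	Native
infantis	ACJ52052.1	100	Native
infantis	ACJ53073.1	100	Native
infantis	ACJ51151.1	100	Foreign
infantis	ACJ53179.1	100	Native
infantis	ACJ52471.1	100	Native
infantis	ACJ51149.1	100	Foreign
infantis	ACJ51552.1	100	Native
infantis	ACJ53224.1	100	Native
infantis	ACJ51550.1	100	Native
infantis	ACJ51553.1	100	Foreign
infantis	ACJ52096.1	100	Foreign
infantis	ACJ52097.1	100	Foreign
infantis	ACJ51554.1	100	Native
infantis	ACJ51425.1	90	Foreign
infantis	ACJ51673.1	90	Native
infantis	ACJ53183.1	90	Native
infantis	ACJ53406.1	90	Native
infantis	ACJ52932.1	90	Native
infantis	ACJ52100.1	90	Native
infantis	ACJ52095.1	90	Foreign
infantis	ACJ51226.1	90	Native
infantis	ACJ53416.1	90	Native
infantis	ACJ53415.1	90	Native
infantis	ACJ51154.1	90	Native
infantis	ACJ51426.1	90	Native
infantis	ACJ51156.1	90	Native
infantis	ACJ53417.1	90	Native
infantis	ACJ51155.1	90	Native
infantis	ACJ51158.1	90	Native
infantis	ACJ51157.1	90	Native
infantis	ACJ51374.1	90	Native
infantis	ACJ51159.1	90	Native
infantis	ACJ51153.1	90	Native
infantis	ACJ53414.1	90	Native
infantis	ACJ53419.1	90	Native
infantis	ACJ53418.1	90	Native
infantis	ACJ51575.1	90	Native
infantis	ACJ51984.1	90	Native
infantis	ACJ51567.1	90	Foreign
infantis	ACJ51985.1	90	Native
infantis	ACJ53244.1	90	Native
infantis	ACJ51983.1	90	Native
suis	AIF90321.1	100	Native
suis	AIF90322.1	100	Native
suis	SDO34397.1	70	Native
suis	SDO30658.1	70	Native
suis	AIF89665.1	70	Native
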
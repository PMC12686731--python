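dataset	tissue	fb_metadata	fb_pipeline	fb_nes	fb_classifier	fb_after_qc
GSE153643	Adipose & liver	4596	6111	6106	5442	5441
GSE123813	Basal	378	1375	1375	595	595
GSE145137	Bladder	273	459	459	322	322
GSE132257	Colorectal	95	348	47	18	18
GSE144735	Colorectal	7650	3145	3140	2190	2189
GSE160269	Esophageal	37213	40048	40048	973	973
GSE109816	Heart	406	0	0	0	0
GSE121893	Heart	973	0	0	0	0
GSE130148	Lung	204	337	311	15	15
GSE131907	Lung	4172	4256	4243	2588	2587
GSE158127	Lung	31032	34746	34673	24440	24437
GSE171524	Lung	21472	22302	20647	9780	9263
GSE150430	Nasopharyngeal	0	31	31	18	18
GSE159929	15 Tissues	15163	21024	21008	15023	15021
GSE201333	24 Tissues	40870	77111	55643	59635	46515
GSE134355	60 Tissues	91356	136695	114471	55901	50590
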
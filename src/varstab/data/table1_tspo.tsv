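id	mutation	PROVEAN	SIFT	PolyPhen2	PhD-SNP	SNAP2	SNPsGO	FATHMM	IMutant3	printed_label
rs764229144	A2D	Neutral	Damaging	possibly damaging	Neutral	Neutral	Neutral	Tolerated	Neutral	N
rs753849621	W5R	Deleterious	Damaging	probably damaging	Neutral	Effect	Neutral	Tolerated	Large decrease of stability	D
rs765728030	A8T	Neutral	Tolerated	probably damaging	Neutral	Neutral	Neutral	Tolerated	Large decrease of stability	N
rs567132675	G10S	Deleterious	Damaging	probably damaging	Neutral	Effect	Neutral	Tolerated	Large decrease of stability	D
rs758845609	L13P	Deleterious	Damaging	probably damaging	Disease	Effect	Neutral	Damaging	Large decrease in stability	D
rs187866832	A14V	Neutral	Tolerated	benign	Neutral	Neutral	Neutral	Tolerated	Neutral	N
rs777431441	V21L	Neutral	Tolerated	benign	Neutral	Neutral	Neutral	Tolerated	Large decrease in stability	N
rs748778969	G22A	Deleterious	Damaging	benign	Disease	Effect	Neutral	Tolerated	Large decrease in stability	D
rs778946143	G28S	Neutral	Tolerated	probably damaging	Neutral	Neutral	Neutral	Tolerated	Large decrease in stability	N
rs775263818	G30D	Neutral	Damaging	probably damaging	Disease	Effect	Neutral	Tolerated	Large decrease in stability	D
rs566580110	R32C	Neutral	Tolerated	probably damaging	Disease	Effect	Neutral	Damaging	Large decrease in stability	D
rs750994845	S41W	Deleterious	Tolerated	benign	Disease	Neutral	Disease	Damaging	Neutral	N
rs550303992	P44L	Deleterious	Damaging	probably damaging	Disease	Effect	Disease	Damaging	Neutral	D
rs566547284	G63S	Neutral	Tolerated	probably damaging	Disease	Effect	Neutral	Tolerated	Large decrease in stability	D
rs139234976	G63D	Deleterious	Damaging	probably damaging	Neutral	Effect	Disease	Tolerated	Large decrease in stability	D
rs756858058	Y65F	Deleterious	Damaging	probably damaging	Disease	Effect	Neutral	Tolerated	Large decrease in stability	D
rs199899658	E70D	Neutral	Tolerated	possibly damaging	Neutral	Neutral	Neutral	Tolerated	Neutral	N
rs749849080	T75I	Deleterious	Damaging	possibly damaging	Neutral	Neutral	Neutral	Tolerated	Neutral	N
rs372235648	A78V	Deleterious	Damaging	probably damaging	Neutral	Effect	Neutral	Tolerated	Neutral	N
rs746919529	G83R	Deleterious	Damaging	probably damaging	Disease	Effect	Disease	Tolerated	Neutral	D
rs754824182	L84F	Deleterious	Tolerated	probably damaging	Disease	Effect	Neutral	Damaging	Large decrease in stability	D
rs142445069	A94V	Deleterious	Damaging	possibly damaging	Disease	Effect	Neutral	Tolerated	Neutral	N
rs775043588	P97L	Deleterious	Damaging	probably damaging	Disease	Effect	Neutral	Tolerated	Neutral	D
rs760110771	A102T	Neutral	Tolerated	benign	Neutral	Neutral	Neutral	Tolerated	Neutral	N
rs775654599	R103Q	Neutral	Damaging	possibly damaging	Neutral	Effect	Neutral	Tolerated	Large decrease of stability	N
rs761543515	Q104E	Neutral	Tolerated	benign	Neutral	Effect	Neutral	Tolerated	Neutral	N
rs143915407	G106V	Deleterious	Tolerated	probably damaging	Disease	Effect	Neutral	Tolerated	Neutral	N
rs752645452	V115I	Neutral	Damaging	benign	Neutral	Neutral	Neutral	Tolerated	Large decrease of stability	N
rs148614502	A119V	Neutral	Tolerated	probably damaging	Neutral	Neutral	Neutral	Tolerated	Neutral	N
rs200880548	A120P	Deleterious	Damaging	possibly damaging	Neutral	Neutral	Neutral	Damaging	Neutral	N
rs779150979	A120G	Deleterious	Tolerated	benign	Disease	Effect	Disease	Tolerated	Large decrease of stability	D
rs780467525	V124M	Neutral	Tolerated	possibly damaging	Neutral	Neutral	Neutral	Tolerated	Large decrease of stability	N
rs373738253	P131L	Deleterious	Tolerated	probably damaging	Disease	Effect	Disease	Tolerated	Large decrease of stability	D
rs773881998	A133T	Deleterious	Damaging	probably damaging	Disease	Effect	Disease	Damaging	Large decrease of stability	D
rs767027529	A134T	Neutral	Tolerated	possibly damaging	Disease	Neutral	Neutral	Tolerated	Large decrease of stability	N
rs775344095	R135C	Neutral	Tolerated	benign	Disease	Neutral	Neutral	Tolerated	Large decrease of stability	N
rs760654235	R135H	Neutral	Tolerated	probably damaging	Neutral	Neutral	Neutral	Tolerated	Large decrease of stability	N
rs757578697	P139T	Deleterious	Damaging	probably damaging	Disease	Effect	Disease	Damaging	Large decrease of stability	D
n/a	P139S	Deleterious	Damaging	probably damaging	Disease	Effect	Disease	Damaging	Large decrease of stability	D
rs6971	A147T	Deleterious	Damaging	benign	Disease	Effect	Neutral	Tolerated	Large decrease of stability	D
rs141002863	A147M	Deleterious	Damaging	benign	Disease	Effect	Neutral	Tolerated	Neutral	N
rs774036527	L150F	Deleterious	Damaging	probably damaging	Disease	Effect	Disease	Damaging	Large decrease of stability	D
rs771545866	V154I	Neutral	Tolerated	benign	Neutral	Neutral	Neutral	Tolerated	Large decrease of stability	N
rs775001391	R156W	Deleterious	Damaging	probably damaging	Disease	Effect	Neutral	Tolerated	Neutral	D
rs375211541	R156Q	Neutral	Tolerated	benign	Disease	Effect	Neutral	Tolerated	Large decrease of stability	N
rs6972	R162H	Neutral	Tolerated	benign	Neutral	Effect	Neutral	Tolerated	Large decrease of stability	N
rs776603192	R165W	Neutral	Damaging	probably damaging	Neutral	Neutral	Neutral	Damaging	Neutral	N
rs761740678	R165Q	Neutral	Tolerated	probably damaging	Neutral	Effect	Neutral	Tolerated	Large decrease of stability	N
rs765102690	R166W	Neutral	Damaging	probably damaging	Neutral	Effect	Neutral	Damaging	Neutral	N
rs8192467	R166L	Neutral	Damaging	benign	Neutral	Effect	Neutral	Tolerated	Neutral	N
rs9333342	E169Q	Neutral	Damaging	possibly damaging	Neutral	Effect	Neutral	Tolerated	Neutral	N
rs568411305	E169V	Neutral	Damaging	possibly damaging	Neutral	Effect	Neutral	Tolerated	Neutral	N
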
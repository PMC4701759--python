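locus_tag	functional_class	orphan_category
WD0261	HEAD	
WD0262	HEAD	
WD0263	BP	
WD0264	BP	
WD0265	REC	
WD0266	MOD	
WD0267	VIR	
WD0268	UK	
WD0269	UK	
WD0270	UK	
WD0565	HEAD	
WD0566	HEAD	
WD0567	HEAD	
WD0568	HEAD	
WD0569	TAIL	
WD0570	TAIL	
WD0571	TAIL	
WD0572	TAIL	
WD0573	REP	
WD0574	REP	
WD0575	REP	
WD0576	MOD	
WD0577	MOD	
WD0578	VIR	
WD0579	VIR	
WD0580	VIR	
WD0581	VIR	
WD0582	VIR	
WD0583	UK	
WD0584	UK	
WD0585	UK	
WD0586	UK	
WD0587	UK	
WD0588	UK	
WD0589	UK	
WD0590	UK	
WD0591	UK	
WD0611	VIR	
WD0612	VIR	
WD0613	VIR	
WD0614	VIR	
WD0615	VIR	
WD0616	UK	
WD0617	UK	
WD0618	UK	
WD0620	UK	
WD0633	BP	
WD0634	BP	
WD0635	REC	
WD0636	VIR	
WP0243	REC	
WP0244	REP	
WP0245	VIR	
WP0246	UK	
WP0247	UK	
WP0248	UK	
WP0249	UK	
WP0250	UK	
WP0297	HEAD	
WP0298	HEAD	
WP0299	BP	
WP0300	MOD	
WP0323	HEAD	
WP0324	HEAD	
WP0325	HEAD	
WP0326	BP	
WP0327	VIR	
WP0328	VIR	
WP0329	UK	
WP0411	HEAD	
WP0412	HEAD	
WP0413	HEAD	
WP0414	BP	
WP0415	BP	
WP0416	TAIL	
WP0417	TAIL	
WP0418	REC	
WP0419	REP	
WP0420	MOD	
WP0421	MOD	
WP0422	VIR	
WP0423	UK	
WP0424	UK	
WP0425	UK	
WP0426	UK	
WP0427	UK	
WP1295	HEAD	
WP1296	HEAD	
WP1297	HEAD	
WP1298	BP	
WP1299	TAIL	
WP1300	TAIL	
WP1301	TAIL	
WP1302	MOD	
WP1303	VIR	
WP1304	VIR	
WP1305	UK	
WP1306	UK	
WP1307	UK	
WP1308	UK	
WP1309	UK	
WP1310	UK	
WP1311	UK	
WP9001	HEAD	PipOrphans
WP9002	REC	PipOrphans
WP9003	REC	PipOrphans
WP9004	UK	PipOrphans
WD9001	VIR	MelOrphans
WD9002	UK	MelOrphans
WD9003	UK	MelOrphans
WD9004	UK	MelOrphans
WD9005	UK	MelOrphans
WA9001	HEAD	Ana/SimOrphans
WA9002	HEAD	Ana/SimOrphans
WA9003	TAIL	Ana/SimOrphans
WA9004	REC	Ana/SimOrphans
WA9005	VIR	Ana/SimOrphans
WA9006	UK	Ana/SimOrphans
WA9007	UK	Ana/SimOrphans
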
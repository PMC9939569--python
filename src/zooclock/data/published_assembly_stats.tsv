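species	phylum	raw_reads	processed_reads	initial_transcripts	final_transcripts	pct_complete_orfs	n50_initial	n50_final
Acartia tonsa	Ar	46728568	30183880	160483	22787	42.7	1452	1959
Acartia clausii	Ar	42990921	23138097	159937	23313	38.7	1377	1897
Calanus helgolandicus	Ar	19503965	17217713	164611	43040	30.2	1366	1570
Centropages hamatus	Ar	21834660	18449434	161672	23278	38.8	1573	2042
Temora longicornis	Ar	38035737	32327268	204478	25724	34.3	1611	2021
Crangon crangon	Ar	19496190	16749098	182017	22686	43.1	2340	2968
Corystes sp.	Ar	20596859	17303099	176664	28738	28.6	1912	2263
Hyperia sp.	Ar	14434862	12339911	127319	17429	21.3	1021	1408
Podon leuckartii	Ar	20965748	18577507	111883	21961	53.5	2535	2477
Evadne nordmanni	Ar	38147607	32851241	125959	14391	51.5	2861	2935
Poecilochaetus sp.	An	19082838	16260294	272460	35984	21.2	1325	1807
Magelona mirabilis	An	16287463	13439540	246407	27690	29.1	1358	2029
Phoronis muelleri	Ph	18102502	16002988	169860	24094	39.8	2000	2532
Oikopleura dioica	Ch	34115579	29875095	113214	19750	49.5	2275	2286
Asterias rubens	Ec	19841332	16895994	127179	17918	33.7	1881	2520
Rathkea octopunctata	Cn	17342954	15271220	77799	16332	61.5	2160	2574
Phialella quadrata	Cn	19314077	17345509	77732	16145	61.6	2338	2626
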
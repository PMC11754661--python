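enhancer_id	source	chrom	start	stop	genes
GH05J000553	GeneHancer	Chr5	553660	554453	EXOC3;CEP72;BRD9;SLC9A3
GH05J000555	GeneHancer	Chr5	555169	557644	PDCD6;CEP72;BRD9;SLC9A3
SE_02_008600693	SEdb2.0	Chr5	505305	558774	SLC9A3;LDC25845
SE_02_024100501	SEdb2.0	Chr5	543481	558675	SLC9A3
SE_02_020700020	SEdb2.0	Chr5	532856	558643	SLC9A3;CEP72
SE_00_002000529	SEdb2.0	Chr5	498817	557908	SLC9A3;LOC25845
SE_00_003600317	SEdb2.0	Chr5	498742	557880	SLC9A3;LOC25845
SE_02_035400733	SEdb2.0	Chr5	473202	554505	SLC9A3;LOC25845;EXOC3;C5ORF55
ENSR00001256048	Ensembl	Chr5	555201	555400	
ENSR00001256049	Ensembl	Chr5	556401	556600	
EH38E2352151	ENCODE	Chr5	553896	554206	SLC9A3;CEP72;EXOC3
EH38E2352153	ENCODE	Chr5	555051	555387	SLC9A3;CEP72;EXOC3
EH38E2352157	ENCODE	Chr5	556903	557118	SLC9A3;CEP72;EXOC3
GH12J132686	GeneHancer	Chr12	132685200	132690084	POLE;PXMP2;ANKLE2;NOC4L;EP400;ZNF891;ZNF84;ZNF140;GOLGA3;CHFR;ZNF605;DDX51;PGAM5;ZNF26;ZNF10
SE_02_116400065	SEdb2.0	Chr12	132684308	132695135	PXMP2;POLE;PGAM5
SE_02_055500763	SEdb2.0	Chr12	132685389	132689520	PXMP2;POLE;PGAM5
SE_02_039600318	SEdb2.0	Chr12	132688822	132789737	ANKLE2;PXMP2;PGAM5;GOLGA3;POLE
SE_02_104301098	SEdb2.0	Chr12	132639038	132685737	POLE;PXMP2;PGAM5;P2RX2;LRCOL1
EH38E1657781	ENCODE	Chr12	132686748	132686912	POLE;PXMP2;ANKLE2
EH38E1657782	ENCODE	Chr12	132686991	132687193	POLE;PXMP2;ANKLE2
EH38E1657785	ENCODE	Chr12	132689268	132689614	POLE;PXMP2;ANKLE2
EH38E1657786	ENCODE	Chr12	132689796	132690144	POLE;PXMP2;ANKLE2
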
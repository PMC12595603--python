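gene_id	gene_name	methy_site	location	diff_methy	correlation	function	pathway
KY. UAContig47.1	SCN9A_3	UAContig47:280	Promoter	Up	Negative	Sodium transport	ion_transport
KY. Chr9.637	SLC10A2	Chr9:4782170	Gene body	Down	Positive	Sodium transport	ion_transport
KY. Chr9.624	SLC24A2	Chr9:4627670	Gene body	Down	Negative	Calcium/potassium/sodium transport	ion_transport
KY. Chr8.402	SLC20A1	Chr8:2357750	Promoter	Down	Positive	Sodium transport	ion_transport
KY. Chr8.1384	PRDX2	Chr8:8238281	Promoter	Down	Positive	Phenylalanine metabolism	faa
KY. Chr8.177	CYP2J2.1	Chr8:837756	Promoter	Up	Positive	Tryptophan metabolism	faa
KY. Chr7.932	SLC8A1	Chr7:7010203	Gene body	Up	Positive	Calcium/sodium transport	ion_transport
KY. Chr5.634	SCN11A	Chr5:4217708	Gene body	Down	Positive	Sodium transport	ion_transport
KY. Chr5.126	AASS	Chr5:983111	Gene body	Up	Negative	Lysine degradation	faa
KY. Chr5.968	KCNK16	Chr5:6604525	Promoter	Up	Positive	Potassium transport	ion_transport
KY. Chr4.1205	SLC12A9	Chr4:6708608	Gene body	Down	Negative	Chlorine/potassium transport	ion_transport
KY. Chr4.1014	KCNIP1	Chr4:5421697	Promoter	Down	Negative	Potassium transport	ion_transport
KY. Chr3.71	SLC12A4	Chr3:398351	Gene body	Down	Positive	Chlorine/potassium transport	ion_transport
KY. Chr3.975	GGT1	Chr3:6523054	Gene body	Up	Positive	Selenoamino acid metabolism	faa
KY. Chr3.311	ALDH3A2	Chr3:1858597	Promoter	Down	Negative	Tyrosine metabolism	faa
KY. Chr2.2019	TRPA1	Chr2:7361442	Promoter	Up	Positive	Calcium transport	ion_transport
KY. Chr2.905	GSTZ1	Chr2:2880336	Promoter	Up	Negative	Glutathione metabolism	faa
KY. Chr11.280	SLC7A8	Chr11:1639491	Gene body	Down	Negative	L-cystine transport	faa
KY. Chr11.479	KCNJ5	Chr11:3038987	Gene body	Down	Negative	Potassium transport	ion_transport
KY. Chr11.297	CLCN5	Chr11:1739243	Gene body	Up	Negative	Chlorine transport	ion_transport
KY. Chr11.1277	PGAM2.1	Chr11:8300541	Gene body	Down	Positive	Biosynthesis of amino acids	faa
KY. Chr1.507	KCNAB2	Chr1:1525161	Gene body	Down	Positive	Potassium transport	ion_transport
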
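# Catalog of putative lipase/esterase and protease coding genes recovered
# from a 40-clone pooled soil fosmid library screen (enzyme class, fosmid,
# contig, gene id, gene size in nt including the stop codon, protein size
# in aa). A gene carrying both domain classes appears under both headings.
enzyme_class	fosmid_id	contig_id	gene_id	nt_length	aa_length
lipase_esterase	F2	C14	Consensus_gene_329	1116	371
lipase_esterase	F2	C14	Consensus_gene_353	852	283
lipase_esterase	F2	C14	Consensus_gene_354	288	95
lipase_esterase	F5	C17	Consensus_gene_420	2115	704
lipase_esterase	F6	C8	Consensus_gene_211	981	326
lipase_esterase	F6	C8	Consensus_gene_212	651	216
lipase_esterase	F8	C18	Consensus_gene_436	2028	675
lipase_esterase	F19	U17	U_42	1086	361
lipase_esterase	F25	C16	Consensus_gene_396	636	211
lipase_esterase	F27	C3	Consensus_gene_87	792	263
lipase_esterase	F28	U36	U_195	1575	524
lipase_esterase	F36	C25	Consensus_gene_553	600	199
protease	F5	C17	Consensus_gene_420	2115	704
protease	F8	C18	Consensus_gene_436	2028	675
protease	F11	C20	Consensus_gene_472	435	144
protease	F11	C20	Consensus_gene_473	828	275
protease	F14	C15	Consensus_gene_359	1098	365
protease	F21	U26	U_145	645	214
protease	F22	C5	Consensus_gene_122	1278	425
protease	F22	C5	Consensus_gene_126	1404	467
protease	F27	C3	Consensus_gene_62	1707	568
protease	F27	C3	Consensus_gene_85	1377	458
protease	F35	U21	U_70	849	282
protease	F36	C9	Consensus_gene_224	1902	633
protease	F36	C9	Consensus_gene_232	1146	381
protease	F38	C21	Consensus_gene_496	1101	366
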
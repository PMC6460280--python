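# Synthetic example domain -> enzyme-category table.
# This is NOT a canonical curated list: supply your own table for real data.
# MK000x accessions are the simulator's planted marker motifs; the PF-style
# rows are a few illustrative lipase/esterase and protease family accessions.
accession	category
MK0001	lipase_esterase
MK0002	protease
PF00561	lipase_esterase
PF01764	lipase_esterase
PF07859	lipase_esterase
PF00082	protease
PF00112	protease
PF01435	protease
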
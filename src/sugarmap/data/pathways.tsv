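# sugarmap-pathways	v1
pathway_id	n_genomes	n_genes
CCM	19	21
Nag	18	15
Grt	17	3
Bgl	9	8
Scr	8	5
Mal	14	13
Ara	6	18
Gal	8	10
Gnt	4	3
Aga	4	8
Man	4	14
Tre	3	6
Xlt	2	6
Rbs	2	6
Nan	1	10
Alg	1	6
Mtl	1	5
Unassigned	19	13
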
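# sugarmap-genomes	v1
alias	full_name	total_genes	sugar_genes	sugar_pathways
MR1	S. oneidensis MR-1	4318	56	4
CN32	S. putrefaciens CN-32	3972	64	4
W3181	S. putrefaciens W3-18-1	4044	64	4
ANA3	S. sp. ANA-3	4111	87	7
MR4	S. sp. MR-4	3924	86	7
MR7	S. sp. MR-7	4006	92	8
Sbal	S. baltica OS155	4307	77	7
OS185	S. baltica OS185	4323	84	8
OS195	S. baltica OS195	4499	80	7
OS223	S. baltica OS223	4250	110	10
Sden	S. denitrificans OS217	3754	58	4
PV4	S. loihica PV-4	3859	59	5
Sama	S. amazonensis SB2B	3645	89	6
Sfri	S. frigidimarina NCIMB 400	4029	70	8
Spie	S. piezotolerans WP-2	4933	68	6
Spea	S. pealeana ANG-SQ1	4241	71	6
Shal	S. halifaxens HAW-EB4	4278	59	5
Ssed	S. sediminis HAW-EB3	4497	47	3
Swoo	S. woodyi ATCC 51908	4880	84	7
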
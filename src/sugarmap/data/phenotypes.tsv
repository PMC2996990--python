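# sugarmap-phenotypes	v1
strain	substrate	predicted	observed	flag
MR1	Glc	+	n	1
MR1	Nag	+	p	0
MR1	Grt	+	p	0
MR1	Bgl	-	n	0
MR1	Scr	-	n	0
MR1	Mal	+	n	1
MR1	Ara	-	n	0
MR1	Gal	-	n	0
MR1	Gnt	-	n	0
MR1	Aga	-	n	0
MR1	Tre	-	n	0
MR1	Mtl	-	n	0
CN32	Glc	-	n	0
CN32	Nag	+	p	0
CN32	Grt	+	p	0
CN32	Bgl	-	n	0
CN32	Scr	-	n	0
CN32	Mal	-	n	0
CN32	Ara	+	p	0
CN32	Gal	-	n	0
CN32	Gnt	-	n	0
CN32	Aga	-	n	0
CN32	Tre	-	n	0
CN32	Mtl	-	n	0
W3181	Glc	-	n	0
W3181	Nag	+	p	0
W3181	Grt	+	p	0
W3181	Bgl	-	n	0
W3181	Scr	-	n	0
W3181	Mal	-	n	0
W3181	Ara	+	nd	0
W3181	Gal	-	n	0
W3181	Gnt	-	nd	0
W3181	Aga	-	nd	0
W3181	Tre	-	n	0
W3181	Mtl	-	nd	0
OS155	Glc	+	p	0
OS155	Nag	+	p	0
OS155	Grt	+	p	0
OS155	Bgl	+	p	0
OS155	Scr	+	p	0
OS155	Mal	+	p	0
OS155	Ara	-	n	0
OS155	Gal	-	n	0
OS155	Gnt	+	p	0
OS155	Aga	-	n	0
OS155	Tre	-	n	0
OS155	Mtl	-	n	0
OS185	Glc	+	p	0
OS185	Nag	+	p	0
OS185	Grt	+	p	0
OS185	Bgl	+	p	0
OS185	Scr	+	p	0
OS185	Mal	+	p	0
OS185	Ara	-	nd	0
OS185	Gal	+	p	0
OS185	Gnt	+	nd	0
OS185	Aga	-	nd	0
OS185	Tre	-	n	0
OS185	Mtl	-	nd	0
OS195	Glc	+	p	0
OS195	Nag	+	p	0
OS195	Grt	+	p	0
OS195	Bgl	+	p	0
OS195	Scr	+	p	0
OS195	Mal	+	p	0
OS195	Ara	-	nd	0
OS195	Gal	-	n	0
OS195	Gnt	+	nd	0
OS195	Aga	-	nd	0
OS195	Tre	-	n	0
OS195	Mtl	-	nd	0
OS223	Glc	+	p	0
OS223	Nag	+	p	0
OS223	Grt	+	p	0
OS223	Bgl	+	p	0
OS223	Scr	+	p	0
OS223	Mal	+	p	0
OS223	Ara	-	nd	0
OS223	Gal	+	p	0
OS223	Gnt	+	nd	0
OS223	Aga	-	nd	0
OS223	Tre	+	p	0
OS223	Mtl	-	nd	0
MR7	Glc	+	p	0
MR7	Nag	+	p	0
MR7	Grt	+	p	0
MR7	Bgl	-	n	0
MR7	Scr	+	p	0
MR7	Mal	+	p	0
MR7	Ara	+	p	0
MR7	Gal	-	n	0
MR7	Gnt	-	n	0
MR7	Aga	+	p	0
MR7	Tre	-	n	0
MR7	Mtl	-	n	0
MR4	Glc	+	p	0
MR4	Nag	+	p	0
MR4	Grt	+	p	0
MR4	Bgl	-	n	0
MR4	Scr	+	p	0
MR4	Mal	+	p	0
MR4	Ara	+	p	0
MR4	Gal	-	n	0
MR4	Gnt	-	n	0
MR4	Aga	+	p	0
MR4	Tre	-	n	0
MR4	Mtl	-	n	0
ANA3	Glc	+	p	0
ANA3	Nag	+	p	0
ANA3	Grt	+	p	0
ANA3	Bgl	-	n	0
ANA3	Scr	+	p	0
ANA3	Mal	+	p	0
ANA3	Ara	+	p	0
ANA3	Gal	-	n	0
ANA3	Gnt	-	n	0
ANA3	Aga	+	p	0
ANA3	Tre	-	n	0
ANA3	Mtl	-	n	0
Sden	Glc	+	w	0
Sden	Nag	+	p	0
Sden	Grt	-	n	0
Sden	Bgl	+	p	0
Sden	Scr	-	n	0
Sden	Mal	+	p	0
Sden	Ara	-	n	0
Sden	Gal	-	n	0
Sden	Gnt	-	n	0
Sden	Aga	-	n	0
Sden	Tre	-	n	0
Sden	Mtl	-	n	0
Sfri	Glc	+	p	0
Sfri	Nag	-	n	0
Sfri	Grt	+	p	0
Sfri	Bgl	+	p	0
Sfri	Scr	+	p	0
Sfri	Mal	+	p	0
Sfri	Ara	-	n	0
Sfri	Gal	-	n	0
Sfri	Gnt	-	n	0
Sfri	Aga	-	n	0
Sfri	Tre	+	p	0
Sfri	Mtl	+	n	1
PV4	Glc	+	w	0
PV4	Nag	+	p	0
PV4	Grt	+	p	0
PV4	Bgl	-	n	0
PV4	Scr	-	n	0
PV4	Mal	+	w	0
PV4	Ara	-	n	0
PV4	Gal	+	w	0
PV4	Gnt	-	n	0
PV4	Aga	-	n	0
PV4	Tre	-	n	0
PV4	Mtl	-	n	0
Sama	Glc	+	p	0
Sama	Nag	+	p	0
Sama	Grt	-	n	0
Sama	Bgl	+	p	0
Sama	Scr	-	n	0
Sama	Mal	+	p	0
Sama	Ara	-	n	0
Sama	Gal	-	n	0
Sama	Gnt	-	n	0
Sama	Aga	+	p	0
Sama	Tre	-	n	0
Sama	Mtl	-	n	0
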
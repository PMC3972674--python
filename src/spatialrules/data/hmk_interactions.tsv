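# Human mitotic kinetochore: protein interaction pairs (one bind rule each;
# symmetric listings already deduplicated).  Each protein uses one specific
# site per partner, named after the partner in lowercase, with two
# exceptions: Zwint shares one "dock" site between Knl1 and Mis12 (it binds
# one *instead of* the other) and Mps1 shares one "dock" site between its
# kinetochore receptors Mis12 and Hec1; each keeps a separate site for its
# remaining partner (Zw10 and BubR1 respectively).  Rules carrying the SAC
# switch only fire while the spindle assembly checkpoint is active.
protein_A	protein_B	site_A	site_B	rate_tag	switch
CenpA	CenpB	cenpb	cenpa	kon
CenpA	CenpN	cenpn	cenpa	kon
CenpA	CenpC	cenpc	cenpa	kon
CenpB	CenpW	cenpw	cenpb	kon
CenpB	CenpQ	cenpq	cenpb	kon
CenpB	CenpU	cenpu	cenpb	kon
CenpB	CenpC	cenpc	cenpb	kon
CenpI	CenpU	cenpu	cenpi	kon
CenpK	CenpO	cenpo	cenpk	kon
CenpK	CenpR	cenpr	cenpk	kon
CenpK	CenpU	cenpu	cenpk	kon
CenpK	CenpN	cenpn	cenpk	kon
CenpM	CenpS	cenps	cenpm	kon
CenpM	CenpU	cenpu	cenpm	kon
CenpM	CenpT	cenpt	cenpm	kon
CenpM	H3	h3	cenpm	kon
CenpO	CenpP	cenpp	cenpo	kon
CenpO	CenpU	cenpu	cenpo	kon
CenpO	CenpQ	cenpq	cenpo	kon
CenpP	CenpU	cenpu	cenpp	kon
CenpP	CenpQ	cenpq	cenpp	kon
CenpQ	CenpU	cenpu	cenpq	kon
CenpR	CenpU	cenpu	cenpr	kon
CenpS	H3	h3	cenps	kon
CenpS	CenpT	cenpt	cenps	kon
CenpS	CenpX	cenpx	cenps	kon
CenpT	H3	h3	cenpt	kon
CenpW	H3	h3	cenpw	kon
Dsn1	Mis12	mis12	dsn1	kon
Dsn1	Nsl1	nsl1	dsn1	kon
Nnf1	Mis12	mis12	nnf1	kon
Nnf1	CenpC	cenpc	nnf1	kon
Nsl1	Spc24	spc24	nsl1	kon
Nsl1	Spc25	spc25	nsl1	kon
Hec1	Nuf2	nuf2	hec1	kon
Nuf2	Spc25	spc25	nuf2	kon
Spc24	Spc25	spc25	spc24	kon
Spc24	CenpT	cenpt	spc24	kon
Cdc20	Mad2	mad2	cdc20	kon	SAC
Cdc20	BubR1	bubr1	cdc20	kon
Cdc20	Apc2	apc2	cdc20	kon
Mad2	Mad1	mad1	mad2	kon	SAC
Mad2	Rod1	rod1	mad2	kon	SAC
Mad2	Zw10	zw10	mad2	kon	SAC
Mad1	Bub1	bub1	mad1	kon	SAC
Mad1	Rod1	rod1	mad1	kon	SAC
Mad1	Zw10	zw10	mad1	kon	SAC
Bub3	Bub1	bub1	bub3	kon
Bub3	BubR1	bubr1	bub3	kon
BubR1	Bub1	bub1	bubr1	kon
BubR1	Knl1	knl1	bubr1	kon
BubR1	Apc3	apc3	bubr1	kon
BubR1	Apc4	apc4	bubr1	kon
BubR1	Apc5	apc5	bubr1	kon
BubR1	Mps1	mps1	bubr1	kon
BubR1	Rod1	rod1	bubr1	kon
BubR1	Zw10	zw10	bubr1	kon
Bub1	Knl1	knl1	bub1	kon
Mps1	Mis12	dock	mps1	kon
Mps1	Hec1	dock	mps1	kon
Zwint	Zw10	zw10	zwint	kon
Zwint	Knl1	dock	zwint	kon
Zwint	Mis12	dock	zwint	kon
Zwilch	Rod1	rod1	zwilch	kon
Zwilch	Zw10	zw10	zwilch	kon
Zw10	Rod1	rod1	zw10	kon
Zw10	Knl1	knl1	zw10	kon
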
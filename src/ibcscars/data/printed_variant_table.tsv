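sample	gene	hgvs_c	hgvs_p	pg	cn_context
IBC1	PIK3CA	c.3140A>G	p.His1047Arg	0	none
IBC2	PIK3CA	c.1633G>A	p.Glu545Lys	0	none
IBC4	ATM	c.3887C>G	p.Pro1296Arg	1	loss
IBC5	BRCA2	c.4963_4964insA	p.Tyr1655Ter	0	loss
IBC7	BRCA2	c.2806_2809delAAAC	p.Ala938Profs	0	cnloh
IBC7	MLH1	c.2146G>A	p.Val716Met	1	loss
IBC8	TP53	c.512A>G	p.Glu171Gly	1	loss
IBC9	BRCA2	c.5682C>G	p.Tyr1894Ter	0	loss
IBC9	RAD51B	c.728A>G	p.Lys243Arg	0	cnloh
IBC9	POLD1	c.1055G>A	p.Arg352His	0	gain
IBC10	BRCA2	c.2T>G	p.Met1?	0	none
IBC11	TP53	c.309C>A	p.Tyr103Ter	0	gain,cnloh
IBC11	BRCA2	c.316+1G>T		0	gain,cnloh
IBC11	RAD51B	c.315+8A>G		1	gain,cnloh
IBC11	MSH6	c.3961A>G	p.Arg1321Gly	1	none
IBC12	TP53	c.659A>G	p.Tyr220Cys	1	cnloh
IBC12	RAD51D	c.899G>A	p.Arg300Gln	1	loss
IBC12	PMS2	c.2186_2187delTC	p.Leu729Glnfs	1	gain
IBC13	TP53	c.712T>G	p.Cys238Gly	1	none
IBC13	BRCA2	c.6988A>G	p.Ile2330Val	1	none
IBC14	TP53	c.586C>T	p.Arg196Ter	1	loss
IBC14	BRCA2	c.8869C>T	p.Gln2957Ter	0	loss
IBC15	PALB2	c.43G>T	p.Glu15Ter	0	cnloh
IBC15	MSH3	c.1567G>A	p.Glu523Lys	1	none
IBC15	MSH3	c.1571A>C	p.Asn524Thr	1	none
IBC16	TP53	c.856G>A	p.Glu286Lys	0	loss,cnloh
IBC16	MSH3	c.2436-5C>G		0	gain
IBC18	TP53	c.626_627delGA	p.Arg209Lysfs	1	loss
IBC18	PIK3CA	c.3140A>T	p.His1047Leu	0	none
IBC18	BRCA2	c.9227G>T	p.Gly3076Val	0	loss
IBC20	TP53	c.578A>T	p.His193Leu	1	none
IBC20	TP53	c.560-2A>C		1	loss
IBC20	PIK3CA	c.1035T>A	p.Asn345Lys	0	none
IBC20	BRCA1	c.3858delT	p.Ser1286Argfs	1	loss
IBC20	MLH3	c.2638C>G	p.Leu880Val	1	none
IBC22	TP53	c.731G>A	p.Gly244Asp	0	loss,cnloh
IBC22	PIK3CA	c.3140A>G	p.His1047Arg	0	none
IBC22	MUS81	c.416G>A	p.Arg139Gln	1	none
IBC22	PMS2	c.2383G>A	p.Asp795Asn	1	none
IBC24	TP53	c.844C>T	p.Arg282Trp	1	loss
IBC24	MSH6	c.1406A>G	p.Tyr469Cys	1	none
IBC26	TP53	c.542G>A	p.Arg181His	1	loss
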
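chrom	pos	exon	coding_change	protein_change	cadd	discovery_fh	validation_fh	sporadic	control
chr5	131931309	13	c.C2014T	p.Q672X		1	0	0	0
chr5	131931460	13	c.2165_2166insT	p.K722fs		1	2	0	0
chr5	131945032	19	c.2980_2983del	p.K994fs		1	0	1	1
chr5	131951735	20	c.3077_3080del	p.K1026fs		1	0	0	0
chr5	131924437	8	c.1110delA	p.L370fs		0	1	2	2
chr5	131944319	17	c.C2731T	p.Q911X		0	0	0	1
chr5	131973850	23	c.C3553T	p.R1185X		0	0	1	0
chr5		13	c.G2177A	p.R726H	25.0	0	1	0	0
chr5			c.C2287T	p.R763C	25.0	0	1	0	0
chr5			c.G3716A	p.R1239Q	25.0	0	1	0	0
chr5		25	c.C3790T	p.L1264F	30.0	0	4	4	3
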
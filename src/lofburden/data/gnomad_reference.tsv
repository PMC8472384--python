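population	n_alleles	variant_set	count
gnomad_ea	19954	all_lof	30
gnomad_ea	19954	zinc_hook_lof	4
gnomad_ea	19954	p.Q672X	0
gnomad_ea	19954	p.K722fs	4
gnomad_ea	19954	p.K994fs	8
gnomad_ea	19954	p.R1185X	1
gnomad_ea	19954	p.L1264F	80
gnomad_all	282670	all_lof	427
gnomad_all	282670	zinc_hook_lof	5
gnomad_all	282670	p.Q672X	1
gnomad_all	282670	p.K722fs	4
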
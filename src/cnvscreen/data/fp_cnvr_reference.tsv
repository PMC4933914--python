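name	chrom	start	end	source_chrom	genes	qtl_count
FP_CNVR1	chr1	83218713	83238102	chrY	EPHB3	1
FP_CNVR2	chr2	55587169	55598367	chrUn		0
FP_CNVR3	chr4	45054839	45072215	chrX	RELN	2
FP_CNVR4	chr4	75028395	75104623	chrUn	GTPBP10	0
FP_CNVR5	chr5	22514133	22563988	chrY		15
FP_CNVR6	chr17	15448739	15477125	chrX		1
FP_CNVR7	chr17	25056695	25119996	chrY	PRAME	0
FP_CNVR8	chr17	50746686	50962760	chrY		4
FP_CNVR9	chr17	51115979	51433906	chrY		7
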
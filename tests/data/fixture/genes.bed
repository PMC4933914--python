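chr1	407999	423000	GENE_FP1
chr2	303749	314250	GENE_FP2
chr2	1511999	1539000	GENE_DIFF1
chr2	782757	797758	GENE_BG1
chr2	885574	900575	GENE_BG2
chr1	718864	733865	GENE_BG3
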
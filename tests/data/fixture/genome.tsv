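chrom	length
chr1	2000000
chr2	2000000
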
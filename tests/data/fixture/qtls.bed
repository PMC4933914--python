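chr1	395499	435500	QTL_FP1
chr2	293499	324500	QTL_FP2
chr2	1493499	1557500	QTL_DIFF1
chr2	296801	336802	QTL_BG1
chr2	862118	902119	QTL_BG2
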
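ebv_beta: 0.5
ebv_sex_effect:
  BW: 0.0
  PWG: 1.5
freq_beta:
- 0.3
- 3.0
freq_bounds:
- 0.001
- 0.5
genome:
- - chr1
  - 2000000
- - chr2
  - 2000000
jitter_probes: 2
length_range:
- 2000
- 200000
loss_fraction: 0.6666666666666666
n_cnv_loci: 8
n_females: 10
n_males: 10
n_related_planted: 1
n_relatedness_pairs: 4
planted_diff:
  chrom: chr2
  cn: 1
  end: 1553999
  loss_freq:
    NEL: 0.73
    TAU: 0.055
  start: 1500000
planted_fp:
- chrom: chr1
  cn: 0
  end: 430000
  fp_class: Y-like
  p_female: 0.98
  p_male: 0.005
  start: 400000
- chrom: chr2
  cn: 3
  end: 320000
  fp_class: X-like
  p_female: 0.4
  p_male: 0.01
  start: 300000
populations:
- NEL
- TAU
probe_spacing: 3000
seed: 11
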
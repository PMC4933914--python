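# Methods

## Coordinates and input conventions

All internal coordinates are 1-based closed intervals
(`length = end − start + 1`), the convention of SNP-array CNV callers
that report the first and last probe of an event; BED input is
converted from 0-based half-open on read and back on write. Chromosome
names are matched by exact string after whitespace trimming — a cohort
mixing `1` and `chr1` fails validation rather than being silently
reconciled. Calls with copy number 2 are rejected at read time: a CNV
call is by definition non-normal, and admitting cn=2 records would
corrupt every downstream frequency.

## CNVR construction

CNVRs are the connected components of the ≥1-bp overlap graph of all
calls on one chromosome; each region spans `min(start)…max(end)` of its
component and is typed `loss`, `gain` or `both` from the direction of
member events. Bookended calls (one ending at p, the next starting at
p+1) do **not** merge: sharing a base pair is the sole criterion.
Typing is per event, not per sample — a sample carrying both a loss and
a gain inside one component makes the region `both`.

Sample QC uses the conventional array-caller thresholds — LRR standard
deviation 0.30, BAF drift 0.01, waviness factor 0.05 — excluding a
sample iff any supplied metric *strictly* exceeds its threshold
(boundary samples are retained; samples without metrics pass with a
warning). Relatedness pruning removes samples until no retained pair
has pi-hat strictly over 0.4, greedily dropping the sample in the most
violating pairs, ties to the lexicographically smallest id. The greedy
rule is a design choice: any vertex-cover-style rule satisfies the
constraint, and this one is deterministic and removes few samples.

Size classes partition CNVRs as small < 10 kb ≤ medium < 100 kb ≤
large. The boundary at exactly 10 kb is genuinely ambiguous in common
usage (both "≤ 10 kb small" and "10 kb ≤ medium" circulate); we place
it in `medium` so that the three classes tile the length axis without
overlap. Per-chromosome coverage is reported per class, with the total
defined as the sum of the class coverages so the partition identity is
exact in floating point; CNV density is events (not regions) per Mbp.

## Segments, states and frequencies

Cutting the call union at every call start and every `end + 1` yields
disjoint segments within which each sample's covering-call set — hence
its copy-number state — is constant. Only covered slices are emitted:
an uncovered slice has frequency zero everywhere and no information.
States use the six-category alphabet A0…A4, >A4 (index `min(cn, 5)`),
with A2 the default for uncovered samples. Assignment requires each
sample's calls to be pairwise non-overlapping ("unique" calls); a
violation is a data error naming the sample, not a silent override.

Segment boundaries can optionally be snapped to the nearest probe
position (ties to the lower coordinate), with each start constrained
past the previous snapped end so the output stays disjoint; segments
squeezed to nothing are dropped with a warning. Nearest-overall (rather
than nearest-probe-inside) was chosen as the simpler deterministic
rule; when calls are themselves probe-delimited the two differ only at
one-probe slivers. Because snapping only relabels boundaries, the
pipeline assigns states on the raw decomposition and carries the matrix
columns through the snap.

Frequency filters encode their comparison per rule, following the
wording each rule is quoted with in the field: "lower than x" rules
(rare-segment removal at 0.01, the common-CNVR rule at 0.05) keep
segments at ≥ x, while the "high frequency" coverage-map rule is a
strict > 0.1.

## The multi-allelic F_ST and the screens

For two groups with state-frequency vectors x, y and sizes N_x, N_y:

    t_i = (x_i N_x + y_i N_y) / (N_x + N_y)
    H_t = 1 − Σ t_i² ,  H_s = ((1 − Σ x_i²) N_x + (1 − Σ y_i²) N_y) / (N_x + N_y)
    F_ST = (H_t − H_s) / H_t

Convexity gives H_s ≤ H_t, so F_ST ∈ [0, 1] for every valid input;
H_t = 0 (both groups monomorphic and identical) is defined as F_ST = 0,
since no differentiation is representable there. The statistic is a
frequency-based fixation index, not a small-sample-corrected estimator:
group sizes enter only as weights.

**Gender (misassembly) screen.** Male-vs-female scans run separately
within each population cohort and a segment is flagged when it trips a
tier in *either* cohort (union). Tier 1 (F_ST > 0.9, strict) captures
the chrY pattern — females, who carry no chrY sequence, show near-fixed
loss calls at an autosomally misplaced chrY region. Tier 2
(F_ST > 0.15, strict) additionally requires female gain frequency above
male gain frequency and male variant frequency below a low-rate bound
(default 0.05, a config parameter: the chrX pattern is qualitative —
"higher gain in females, low variant rates in males" — so the bound
must be a tunable). Flagged segments merge when overlapping or
bookended; each merged FP CNVR is classed `Y-like` when female loss
enrichment dominates and `X-like` when female gain enrichment does,
with the dominant direction reported. Sequence-level confirmation
(similarity search of the region against another assembly) is outside
the package's scope.

**Breed screen.** The cutoff is the nearest-rank (1 − 0.005) empirical
quantile of the between-population segment F_ST distribution, or a
fixed override (e.g. 0.14); selection is inclusive (≥ cutoff), and
segments with F_ST = 0 are never selected. Differential and common
CNVRs are flagged when they intersect a known FP CNVR — the audit that
prevents misassembly artifacts from being reported as biology.

## Association scan

Extreme groups are the top and bottom `n_per_tail` (default 200)
samples by EBV, ties broken by sample id, with a sex-count report per
group. Per segment, the 2×2 table of loss carriers (state < A2) versus
others across the two groups is tested with Pearson's chi-square, 1 df,
no continuity correction and no cell-count minimum; segments with zero
loss carriers overall are skipped (the test is undefined), and
segments where everyone is a carrier score χ² = 0. Raw p < 0.01 flags
significance with no multiple-testing correction — deliberately, since
the scan's purpose here is to audit how many *artifact* segments cross
a conventional screening threshold, and any correction would apply
equally to artifact and genuine segments. Significant segments are
annotated with ≥1-bp intersection against the FP-CNVR set after the
scan (audit-after, not exclude-before), which is what exposes the
pitfall: under sex-balanced groups FP segments stay quiet; under
sex-unbalanced groups they dominate the top hits.

## Synthetic cohorts

The generator emits calls directly — the screens consume calls, so
simulating array intensity signal would add nothing the pipeline can
see. Defaults describe the study conditions end to end:

* genome: 5 toy chromosomes of 10 Mbp, one probe per 3 kb;
* cohort: 2 populations × (200 males + 200 females);
* 60 shared polymorphic loci, frequency ~ Beta(0.3, 3) truncated to
  [0.001, 0.5], length log-uniform 2–200 kb, loss:gain 2:1; each sample
  carries each locus independently (Bernoulli), with call boundaries
  jittered by up to ±2 probes and snapped to the grid so call overlap
  induces realistic short segments;
* three planted misassembly artifacts: two Y-like regions (loss cn=0,
  carrier probability 0.98 in females, 0.005 in males) and one X-like
  region (gain cn=3, 0.40 / 0.01). The Y-like probabilities encode
  "near-fixed female loss": a female carries no chrY sequence at all,
  so her call rate at a truly misplaced region approaches the caller's
  sensitivity, and the expected between-sex F_ST (≈ 0.95) clears the
  0.9 tier with margin — at 0.95/0.01 the formula gives only ≈ 0.885,
  which no screen using the 0.9 threshold could flag;
* one planted differential deletion (cn=1, 54 kb) at loss frequency
  0.73 in the indicine-like and 0.055 in the taurine-like population —
  the midpoints of the per-segment ranges reported for the validated
  chr5 deletion (66.33–79.93% and 4.75–6.32%);
* EBV model: trait = 0.5·(deletion carrier) + sex_effect·(male) +
  N(0, 1), with sex effect 0 for the BW-like trait and 1.5 for the
  PWG-like trait, so BW extremes are sex-balanced and PWG extremes
  heavily unbalanced;
* a relatedness table with a few planted pi-hat > 0.4 pairs, QC metrics
  drawn inside the passing ranges, and gene/QTL annotations planted
  inside and outside every truth interval.

Planted regions (artifacts and the deletion) assign carriers by exact
count `round(p·n)` within each population-sex stratum via a seeded
permutation: the ground truth is then consistent with the emitted call
set by construction, and the planted frequencies are realised exactly
rather than to within binomial noise. Background loci stay Bernoulli.
Background loci that would overlap a planted interval are discarded at
layout time so each truth region maps to segments of known frequency.
One global seed feeds a named random stream per generator stage
(layout, carriers, jitter, QC, EBV, relatedness, features), so adding a
stage never perturbs earlier draws and identical configs are
byte-identical on disk.

What the generator does **not** emulate — and what passing tests on it
therefore cannot show — includes linkage disequilibrium between loci,
pedigree structure beyond the pairwise pi-hat table, caller boundary
uncertainty beyond uniform probe jitter, genomic waves or batch effects
in call quality, and sex differences on real sex chromosomes (all toy
chromosomes are autosome-like; the artifacts are planted patterns, not
emergent miscalls).

## Numerical and scale choices

Problem sizes were chosen so the full suite runs in seconds while
keeping every statistical check meaningful: the F_ST oracle grid uses
10⁴ random six-category frequency pairs (agreement to 1e−12 against
plain direct summation), the segmentation oracle 200 random instances
of ≤ 40 calls × ≤ 20 samples on a 20 kb toy chromosome against
per-base brute force, the null calibration 5,000 segments at n = 200
per group (empirical type-I within 3 Monte-Carlo SE of 0.01), and the
frequency-recovery check uses a ±3-binomial-SE band floored at 4
counts, since rare-locus carrier counts are Poisson-like and the
normal band is too narrow below ~5 expected carriers. Frequency-vector
validation tolerates 1e−9 in the sum; F_ST is clamped to [0, 1] only
against float round-off. Ties are deterministic everywhere: probe
snapping to the lower coordinate, relatedness and extreme-group
selection by lexicographic sample id, nearest-rank quantiles.

## Known limitations

The package trusts the caller's integer copy numbers; it does not
re-genotype from signal, so systematically miscalled states propagate.
The FP screen's tier thresholds are frequency-based and need adequate
group sizes (tens per sex) before F_ST estimates stabilise. CNVR typing
by member events cannot distinguish a bi-allelic loss/gain locus from
two overlapping distinct events. The chi-square scan is uncorrected for
relatedness or population structure — it is an audit instrument, not a
GWAS replacement.
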
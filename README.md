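# cnvscreen

Post-calling analysis of SNP-array CNV call sets for cattle-scale
cohorts: CNV region (CNVR) construction, decomposition into
frequency-homogeneous CNV segments, screening for **false-positive
CNVRs caused by sex-chromosome misassembly**, definition of
lineage-differential and common CNVRs between populations, and a
chi-square CNV association scan that quantifies how those artifacts
corrupt trait mapping.

It is aimed at quantitative geneticists who already have per-sample CNV
calls (e.g. PennCNV `rawcnv` output) and want the population-level
post-processing: the package never touches raw LRR/BAF signal.

## The problem and the statistic

Draft reference assemblies occasionally scaffold chrX- or chrY-derived
sequence onto autosomes. At such a region, array probes see one copy in
males and zero (chrY) or two (chrX) in females, so the caller emits
recurrent, strongly sex-skewed CNVs that are artifacts of the assembly,
not biology. The screen detects them by treating each CNV segment's
categorical copy-number states A0, A1, A2, A3, A4, >A4 (A2 = normal
diploid) as alleles of a multi-allelic locus and computing a weighted
F_ST between groups X and Y of sizes N_x, N_y with state frequencies
x_i, y_i:

    t_i  = (x_i·N_x + y_i·N_y) / (N_x + N_y)
    H_t  = 1 − Σ t_i²
    H_s  = ((1 − Σ x_i²)·N_x + (1 − Σ y_i²)·N_y) / (N_x + N_y)
    F_ST = (H_t − H_s) / H_t        (defined as 0 when H_t = 0)

Between males and females, segments with F_ST above 0.9 show the chrY
pattern (near-fixed loss in females); segments above 0.15 with
female-enriched gains and quiet males show the chrX pattern. Flagged
segments merge into false-positive (FP) CNVRs. The same scan between
two populations, cut at the 0.5% upper tail, yields
lineage-differential CNVRs; segments at frequency ≥ 0.05 in every
population yield common CNVRs. Finally, a Pearson chi-square scan of
loss-carrier counts between extreme-EBV groups shows that FP CNVRs
reach spurious significance exactly when the extreme groups are
sex-unbalanced.

A cohort-scale synthetic-data generator with planted ground truth
(`cnvscreen.simulate`) makes every stage testable without cohort
genotypes, and a curated table of nine validated FP-CNVR coordinates
ships with the package (`cnvscreen.load_fp_reference()`).

## Worked example

```python
import cnvscreen as cs

sim = cs.simulate_cohort(cs.default_config(seed=1))       # 2 pops x 200M + 200F
cohort = cs.segment_cohort(sim.calls, sim.samples, sim.probes)
print(f"{len(sim.calls)} calls, {len(cohort.cnvrs)} CNVRs, {len(cohort.segments)} segments")

fst_by, freq_by, fp = cs.gender_screen(cohort, sim.samples)
for r in fp:
    print(f"{r.chrom}:{r.start}-{r.end}  {r.fp_class:7s} {r.direction:15s} peak F_ST={r.peak_fst:.3f}")

pops = cs.population_groups(sim.samples)
scan = cs.fst_scan(cohort.matrix, pops["NEL"], pops["TAU"])
res = cs.breed_differential(scan, list(cohort.segments), fp_cnvrs=fp)
print(f"breed cutoff (0.5% tail) = {res.cutoff:.4f}; {len(res.cnvrs)} differential CNVRs")
```

prints

```
4427 calls, 48 CNVRs, 319 segments
chr2:2998500-3058500  Y-like  loss_in_female  peak F_ST=0.951
chr3:6499500-6538500  Y-like  loss_in_female  peak F_ST=0.951
chr4:2200500-2230500  X-like  gain_in_female  peak F_ST=0.233
breed cutoff (0.5% tail) = 0.0089; 2 differential CNVRs
```

The three flagged regions are exactly the generator's planted
misassembly artifacts: the two Y-like regions carry near-fixed female
loss calls (F_ST 0.951 between sexes), the X-like one female-enriched
gains. The differential scan's tail picks up the planted deletion at
chr5:7999500-8053500, whose recovered loss frequency is 73.0% in the
indicine-like population versus 5.5% in the taurine-like one
(segment F_ST ≈ 0.48).

The same pipeline runs from the shell on any call set:

```
cnvscreen simulate --seed 1 --tiny --out-dir sim/
cnvscreen all --calls sim/calls.tsv --samples sim/samples.tsv \
    --probes sim/probes.tsv --genome sim/genome.tsv \
    --genes sim/genes.bed --qtls sim/qtls.bed \
    --trait PWG --n-per-tail 10 --out-dir reports/
```

## Layout

| module | contents |
| --- | --- |
| `cnvscreen.io` | readers/writers and domain records (calls, samples, probes, features, relatedness) |
| `cnvscreen.cnvr` | QC and relatedness filters, CNVR merge and typing, size classes, per-chromosome summaries, ≥1-bp feature overlap |
| `cnvscreen.segments` | boundary decomposition, probe snapping, state matrix, frequencies and frequency filters |
| `cnvscreen.fst` | the multi-allelic F_ST, gender (FP) screen, breed-differential and common CNVRs |
| `cnvscreen.association` | extreme-EBV groups and the chi-square loss scan |
| `cnvscreen.simulate` | synthetic cohorts with planted ground truth |
| `cnvscreen.pipeline`, `cnvscreen.cli` | stage composition and the `cnvscreen` command |

See `docs/methods.md` for the model, parameter defaults and the
generator's scope and limitations.
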
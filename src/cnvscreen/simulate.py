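"""Synthetic cohort generator with planted ground truth.

Emits cohort-scale per-sample CNV call sets (plus sample metadata, probe
map, annotations and relatedness) that exercise every pipeline stage:

* shared polymorphic CNV loci whose population frequencies follow a
  truncated Beta spectrum, carried independently per sample with
  probe-snapped, jittered boundaries (so call overlap induces realistic
  short segments);
* sex-misassembly artifacts — chrY-like regions with near-fixed loss
  calls in females and chrX-like regions with female-enriched gains;
* one population-differential deletion with stated per-population loss
  frequencies;
* an EBV model (carrier effect at the differential locus + sex effect +
  unit Gaussian noise) yielding one sex-neutral and one sex-linked trait.

Planted regions (artifacts and the differential deletion) assign their
carriers by exact count ``round(p * n)`` within each population-sex
stratum via a seeded permutation, so the emitted call set realises the
configured frequencies by construction; background loci use independent
Bernoulli draws.  Calls are generated directly rather than via simulated
array signal: the screens operate on calls, and that is the contract the
generator must satisfy.

A single global seed drives one named random stream per generator stage,
so adding a stage never perturbs earlier stages' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io import (
    CnvCall,
    Feature,
    GenomeLayout,
    ProbeMap,
    RelatednessPair,
    SampleMeta,
    write_cnv_calls,
    write_table,
)

__all__ = [
    "PlantedFp",
    "PlantedDiff",
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "default_config",
    "tiny_config",
    "simulate_cohort",
    "write_fixture",
]

_STAGES = {"layout": 0, "carriers": 1, "jitter": 2, "qc": 3, "ebv": 4, "relatedness": 5, "features": 6}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES[stage],)))


@dataclass(frozen=True)
class PlantedFp:
    """A sex-misassembly artifact region to plant."""

    chrom: str
    start: int
    end: int
    fp_class: str  # Y-like | X-like
    p_female: float
    p_male: float
    cn: int  # copy number emitted for carriers

    def __post_init__(self) -> None:
        if self.fp_class not in ("Y-like", "X-like"):
            raise ValueError(f"fp_class must be Y-like or X-like, got {self.fp_class!r}")
        for p in (self.p_female, self.p_male):
            if not 0.0 <= p <= 1.0:
                raise ValueError("carrier probability outside [0,1]")


@dataclass(frozen=True)
class PlantedDiff:
    """A population-differential deletion to plant."""

    chrom: str
    start: int
    end: int
    loss_freq: Mapping[str, float]  # population -> carrier probability
    cn: int = 1

    def __post_init__(self) -> None:
        for p in self.loss_freq.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("loss frequency outside [0,1]")


def _default_genome() -> GenomeLayout:
    return GenomeLayout(tuple((f"chr{i}", 10_000_000) for i in range(1, 6)))


def _default_fp() -> tuple[PlantedFp, ...]:
    # Y-like: near-fixed female loss (females carry no chrY sequence at
    # all, so the call rate approaches call sensitivity); X-like:
    # female-enriched gain with quiet males.
    return (
        PlantedFp("chr2", 3_000_000, 3_060_000, "Y-like", p_female=0.98, p_male=0.005, cn=0),
        PlantedFp("chr3", 6_500_000, 6_540_000, "Y-like", p_female=0.98, p_male=0.005, cn=0),
        PlantedFp("chr4", 2_200_000, 2_230_000, "X-like", p_female=0.40, p_male=0.01, cn=3),
    )


def _default_diff() -> PlantedDiff:
    return PlantedDiff(
        "chr5", 8_000_000, 8_053_999, loss_freq={"NEL": 0.73, "TAU": 0.055}, cn=1
    )


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic cohort."""

    seed: int
    genome: GenomeLayout = field(default_factory=_default_genome)
    populations: tuple[str, ...] = ("NEL", "TAU")
    n_males: int = 200  # per population
    n_females: int = 200  # per population
    n_cnv_loci: int = 60
    freq_beta: tuple[float, float] = (0.3, 3.0)
    freq_bounds: tuple[float, float] = (0.001, 0.5)
    length_range: tuple[int, int] = (2_000, 200_000)  # log-uniform, bp
    loss_fraction: float = 2.0 / 3.0  # loss:gain = 2:1
    planted_fp: tuple[PlantedFp, ...] = field(default_factory=_default_fp)
    planted_diff: PlantedDiff | None = field(default_factory=_default_diff)
    probe_spacing: int = 3_000
    jitter_probes: int = 2  # boundary jitter, +/- probes
    ebv_beta: float = 0.5
    ebv_sex_effect: Mapping[str, float] = field(
        default_factory=lambda: {"BW": 0.0, "PWG": 1.5}
    )
    n_relatedness_pairs: int = 10
    n_related_planted: int = 2

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")
        names = set(self.genome.names)
        planted = list(self.planted_fp) + ([self.planted_diff] if self.planted_diff else [])
        for r in planted:
            if r.chrom not in names:
                raise ValueError(f"planted interval on unknown chromosome {r.chrom!r}")
            if not (1 <= r.start <= r.end <= self.genome.length(r.chrom)):
                raise ValueError(f"planted interval {r.chrom}:{r.start}-{r.end} outside genome")
        for i, a in enumerate(planted):
            for b in planted[i + 1 :]:
                if a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
                    raise ValueError("planted intervals overlap")
        if not 0.0 <= self.loss_fraction <= 1.0:
            raise ValueError("loss_fraction outside [0,1]")


def default_config(seed: int) -> SimConfig:
    """The default study cohort: 2 populations x (200 males + 200 females)."""
    return SimConfig(seed=seed)


def tiny_config(seed: int) -> SimConfig:
    """A 40-sample, 2-chromosome cohort for fast tests and the shipped fixture."""
    genome = GenomeLayout((("chr1", 2_000_000), ("chr2", 2_000_000)))
    return SimConfig(
        seed=seed,
        genome=genome,
        n_males=10,
        n_females=10,
        n_cnv_loci=8,
        planted_fp=(
            PlantedFp("chr1", 400_000, 430_000, "Y-like", p_female=0.98, p_male=0.005, cn=0),
            PlantedFp("chr2", 300_000, 320_000, "X-like", p_female=0.40, p_male=0.01, cn=3),
        ),
        planted_diff=PlantedDiff(
            "chr2", 1_500_000, 1_553_999, loss_freq={"NEL": 0.73, "TAU": 0.055}, cn=1
        ),
        n_relatedness_pairs=4,
        n_related_planted=1,
    )


@dataclass(frozen=True)
class LocusTruth:
    chrom: str
    start: int
    end: int
    cn: int
    true_freq: float
    carriers: frozenset
    isolated: bool  # overlaps no other locus or planted region


@dataclass(frozen=True)
class RegionTruth:
    name: str
    chrom: str
    start: int
    end: int
    fp_class: str | None
    cn: int
    carrier_prob: Mapping[str, float]  # stratum label -> probability
    carriers: frozenset


@dataclass(frozen=True)
class GroundTruth:
    fp_regions: tuple[RegionTruth, ...]
    diff_region: RegionTruth | None
    loci: tuple[LocusTruth, ...]


@dataclass(frozen=True)
class SimResult:
    calls: tuple[CnvCall, ...]
    samples: tuple[SampleMeta, ...]
    probes: ProbeMap
    genome: GenomeLayout
    features: tuple[Feature, ...]
    relatedness: tuple[RelatednessPair, ...]
    truth: GroundTruth
    config: SimConfig


def _make_probes(config: SimConfig) -> ProbeMap:
    pos = {}
    for chrom, length in config.genome.chroms:
        half = config.probe_spacing // 2
        pos[chrom] = np.arange(half, length + 1, config.probe_spacing, dtype=np.int64)
    return ProbeMap(pos)


def _nearest_idx(arr: np.ndarray, pos: int) -> int:
    i = int(np.searchsorted(arr, pos))
    if i == 0:
        return 0
    if i == arr.size:
        return arr.size - 1
    return i - 1 if (pos - arr[i - 1]) <= (arr[i] - pos) else i


def _overlaps(a_chrom, a_start, a_end, regions) -> bool:
    return any(
        a_chrom == r.chrom and a_start <= r.end and r.start <= a_end for r in regions
    )


def simulate_cohort(config: SimConfig) -> SimResult:
    """Generate the cohort.  Deterministic: same config (incl. seed) -> same output."""
    probes = _make_probes(config)
    genome = config.genome

    # -- samples ----------------------------------------------------------
    samples_plan: list[tuple[str, str, str]] = []  # (sample_id, sex, population)
    for pop in config.populations:
        for i in range(config.n_males):
            samples_plan.append((f"{pop}_M{i + 1:04d}", "male", pop))
        for i in range(config.n_females):
            samples_plan.append((f"{pop}_F{i + 1:04d}", "female", pop))
    sample_ids = [sid for sid, _, _ in samples_plan]
    strata: dict[tuple[str, str], list[str]] = {}
    for sid, sex, pop in samples_plan:
        strata.setdefault((pop, sex), []).append(sid)

    # -- locus layout -----------------------------------------------------
    rng_layout = _rng(config.seed, "layout")
    planted_regions = list(config.planted_fp) + (
        [config.planted_diff] if config.planted_diff else []
    )
    lo_len, hi_len = config.length_range
    a, b = config.freq_beta
    f_lo, f_hi = config.freq_bounds
    chrom_names = genome.names
    loci: list[dict] = []
    for _ in range(config.n_cnv_loci):
        placed = None
        for _attempt in range(50):
            chrom = chrom_names[int(rng_layout.integers(len(chrom_names)))]
            length = int(np.exp(rng_layout.uniform(np.log(lo_len), np.log(hi_len))))
            l_chrom = genome.length(chrom)
            if length >= l_chrom:
                continue
            start = int(rng_layout.integers(1, l_chrom - length + 1))
            end = start + length - 1
            # keep planted truth intervals clean of background loci
            if _overlaps(chrom, start, end, planted_regions):
                continue
            placed = (chrom, start, end)
            break
        if placed is None:
            continue
        freq = float(np.clip(rng_layout.beta(a, b), f_lo, f_hi))
        cn = 1 if rng_layout.uniform() < config.loss_fraction else 3
        chrom, start, end = placed
        arr = probes[chrom]
        i0, i1 = _nearest_idx(arr, start), _nearest_idx(arr, end)
        if i1 <= i0:
            i1 = min(i0 + 1, arr.size - 1)
        loci.append({"chrom": chrom, "i0": i0, "i1": i1, "cn": cn, "freq": freq})

    # -- carriers ---------------------------------------------------------
    rng_carriers = _rng(config.seed, "carriers")

    def exact_carriers(prob_by_stratum: Mapping[tuple[str, str], float]) -> frozenset:
        chosen: set[str] = set()
        for (pop, sex), members in strata.items():
            p = prob_by_stratum.get((pop, sex), 0.0)
            k = int(round(p * len(members)))
            if k > 0:
                perm = rng_carriers.permutation(len(members))[:k]
                chosen.update(members[j] for j in perm)
        return frozenset(chosen)

    fp_truth: list[RegionTruth] = []
    for r_i, r in enumerate(config.planted_fp):
        probs = {
            (pop, "female"): r.p_female for pop in config.populations
        } | {(pop, "male"): r.p_male for pop in config.populations}
        carriers = exact_carriers(probs)
        arr = probes[r.chrom]
        s, e = int(arr[_nearest_idx(arr, r.start)]), int(arr[_nearest_idx(arr, r.end)])
        fp_truth.append(
            RegionTruth(
                name=f"FP{r_i + 1}",
                chrom=r.chrom,
                start=s,
                end=e,
                fp_class=r.fp_class,
                cn=r.cn,
                carrier_prob={"female": r.p_female, "male": r.p_male},
                carriers=carriers,
            )
        )

    diff_truth: RegionTruth | None = None
    if config.planted_diff:
        d = config.planted_diff
        probs = {
            (pop, sex): d.loss_freq.get(pop, 0.0)
            for pop in config.populations
            for sex in ("male", "female")
        }
        carriers = exact_carriers(probs)
        arr = probes[d.chrom]
        s, e = int(arr[_nearest_idx(arr, d.start)]), int(arr[_nearest_idx(arr, d.end)])
        diff_truth = RegionTruth(
            name="DIFF1",
            chrom=d.chrom,
            start=s,
            end=e,
            fp_class=None,
            cn=d.cn,
            carrier_prob=dict(d.loss_freq),
            carriers=carriers,
        )

    locus_carriers: list[frozenset] = []
    for locus in loci:
        mask = rng_carriers.uniform(size=len(sample_ids)) < locus["freq"]
        locus_carriers.append(frozenset(np.array(sample_ids)[mask]))

    # -- emit calls (planted first, then loci in order; per-sample overlap
    #    conflicts drop the later-drawn call) ------------------------------
    rng_jitter = _rng(config.seed, "jitter")
    taken: dict[str, dict[str, list[tuple[int, int]]]] = {sid: {} for sid in sample_ids}

    def try_emit(sid: str, chrom: str, start: int, end: int, cn: int, n_probes: int) -> CnvCall | None:
        lst = taken[sid].setdefault(chrom, [])
        if any(start <= e and s <= end for s, e in lst):
            return None
        lst.append((start, end))
        return CnvCall(sample_id=sid, chrom=chrom, start=start, end=end, cn=cn, n_probes=n_probes)

    calls: list[CnvCall] = []
    for region in fp_truth + ([diff_truth] if diff_truth else []):
        for sid in sorted(region.carriers):
            c = try_emit(sid, region.chrom, region.start, region.end, region.cn,
                         _probe_count(probes, region.chrom, region.start, region.end))
            if c:
                calls.append(c)

    realized: list[frozenset] = []
    for locus, carriers in zip(loci, locus_carriers):
        arr = probes[locus["chrom"]]
        i0, i1 = locus["i0"], locus["i1"]
        im = (i0 + i1) // 2
        emitted: set[str] = set()
        for sid in sorted(carriers):
            j = config.jitter_probes
            js = int(np.clip(i0 + rng_jitter.integers(-j, j + 1), 0, im))
            je = int(np.clip(i1 + rng_jitter.integers(-j, j + 1), im, arr.size - 1))
            c = try_emit(sid, locus["chrom"], int(arr[js]), int(arr[je]), locus["cn"], je - js + 1)
            if c:
                calls.append(c)
                emitted.add(sid)
        realized.append(frozenset(emitted))

    # -- locus isolation flags (for clean frequency-recovery checks) ------
    all_regions = [
        (r.chrom, r.start, r.end) for r in fp_truth + ([diff_truth] if diff_truth else [])
    ]
    pad = (config.jitter_probes + 1) * config.probe_spacing
    locus_truth: list[LocusTruth] = []
    for k, (locus, emitted) in enumerate(zip(loci, realized)):
        arr = probes[locus["chrom"]]
        s, e = int(arr[locus["i0"]]), int(arr[locus["i1"]])
        isolated = True
        for k2, other in enumerate(loci):
            if k2 == k:
                continue
            if other["chrom"] == locus["chrom"]:
                o_s, o_e = int(arr[other["i0"]]) - pad, int(arr[other["i1"]]) + pad
                if s <= o_e and o_s <= e:
                    isolated = False
                    break
        locus_truth.append(
            LocusTruth(
                chrom=locus["chrom"],
                start=s,
                end=e,
                cn=locus["cn"],
                true_freq=locus["freq"],
                carriers=emitted,
                isolated=isolated,
            )
        )

    # -- sample metadata: QC and EBV traits -------------------------------
    rng_qc = _rng(config.seed, "qc")
    rng_ebv = _rng(config.seed, "ebv")
    diff_carriers = diff_truth.carriers if diff_truth else frozenset()
    samples: list[SampleMeta] = []
    for sid, sex, pop in samples_plan:
        qc = {
            "lrr_sd": round(float(rng_qc.uniform(0.10, 0.28)), 4),
            "baf_drift": round(float(rng_qc.uniform(0.0, 0.008)), 5),
            "waviness": round(float(rng_qc.uniform(0.0, 0.04)), 4),
        }
        traits = {}
        for trait, sex_eff in config.ebv_sex_effect.items():
            value = (
                config.ebv_beta * (sid in diff_carriers)
                + sex_eff * (sex == "male")
                + float(rng_ebv.normal())
            )
            traits[trait] = round(value, 6)
        samples.append(SampleMeta(sample_id=sid, sex=sex, population=pop, traits=traits, qc=qc))

    # -- relatedness ------------------------------------------------------
    rng_rel = _rng(config.seed, "relatedness")
    pairs: list[RelatednessPair] = []
    seen_pairs: set[tuple[str, str]] = set()
    n_random = config.n_relatedness_pairs
    n_high = config.n_related_planted
    while len(pairs) < n_random + n_high and len(seen_pairs) < len(sample_ids) ** 2:
        i, j = rng_rel.integers(len(sample_ids)), rng_rel.integers(len(sample_ids))
        if i == j:
            continue
        key = (sample_ids[min(i, j)], sample_ids[max(i, j)])
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        high = len(pairs) >= n_random
        pi = float(rng_rel.uniform(0.45, 0.7)) if high else float(rng_rel.uniform(0.02, 0.2))
        pairs.append(RelatednessPair(key[0], key[1], round(pi, 4)))

    # -- features: a gene and a QTL inside each truth interval, plus
    #    background annotations elsewhere ---------------------------------
    rng_feat = _rng(config.seed, "features")
    features: list[Feature] = []
    truth_regions = fp_truth + ([diff_truth] if diff_truth else [])
    for i, r in enumerate(truth_regions):
        span = r.end - r.start + 1
        g_start = r.start + span // 4
        g_end = min(r.end, g_start + max(span // 2, 1_000))
        features.append(Feature(r.chrom, g_start, g_end, f"GENE_{r.name}", "gene"))
        q_start = max(1, r.start - 5_000)
        q_end = min(genome.length(r.chrom), r.end + 5_000)
        features.append(
            Feature(r.chrom, q_start, q_end, f"QTL_{r.name}", "qtl", {"trait": "BW"})
        )
    for i in range(3):
        chrom = chrom_names[int(rng_feat.integers(len(chrom_names)))]
        start = int(rng_feat.integers(1, genome.length(chrom) - 20_000))
        features.append(Feature(chrom, start, start + 15_000, f"GENE_BG{i + 1}", "gene"))
    for i in range(2):
        chrom = chrom_names[int(rng_feat.integers(len(chrom_names)))]
        start = int(rng_feat.integers(1, genome.length(chrom) - 50_000))
        features.append(
            Feature(chrom, start, start + 40_000, f"QTL_BG{i + 1}", "qtl", {"trait": "PWG"})
        )

    truth = GroundTruth(
        fp_regions=tuple(fp_truth),
        diff_region=diff_truth,
        loci=tuple(locus_truth),
    )
    return SimResult(
        calls=tuple(calls),
        samples=tuple(samples),
        probes=probes,
        genome=genome,
        features=tuple(features),
        relatedness=tuple(pairs),
        truth=truth,
        config=config,
    )


def _probe_count(probes: ProbeMap, chrom: str, start: int, end: int) -> int:
    arr = probes[chrom]
    return int(np.searchsorted(arr, end, side="right") - np.searchsorted(arr, start))


_PENN_STATE_OF_CN = {0: 1, 1: 2, 3: 5, 4: 6}


def _rawcnv_line(c: CnvCall) -> str:
    state = _PENN_STATE_OF_CN.get(c.cn, 6)
    length = c.end - c.start + 1
    n = c.n_probes or 1
    return (
        f"{c.chrom}:{c.start}-{c.end}\tnumsnp={n}\tlength={length}\t"
        f"state{state},cn={c.cn}\t{c.sample_id}\tstartsnp=p{c.start}\tendsnp=p{c.end}"
    )


def write_fixture(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write all pipeline-conformant input files plus truth.

    Returns a name -> path map of everything written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate_cohort(config)
    paths: dict[str, Path] = {}

    ordered_calls = sorted(sim.calls, key=lambda c: (c.sample_id, c.chrom, c.start))
    paths["calls.rawcnv"] = out_dir / "calls.rawcnv"
    paths["calls.rawcnv"].write_text("".join(_rawcnv_line(c) + "\n" for c in ordered_calls))
    paths["calls.tsv"] = out_dir / "calls.tsv"
    write_cnv_calls(ordered_calls, paths["calls.tsv"])

    paths["samples.tsv"] = out_dir / "samples.tsv"
    rows = [
        {
            "sample_id": s.sample_id,
            "sex": s.sex,
            "population": s.population,
            "qc_lrr_sd": s.qc["lrr_sd"],
            "qc_baf_drift": s.qc["baf_drift"],
            "qc_waviness": s.qc["waviness"],
            **{t: v for t, v in sorted(s.traits.items())},
        }
        for s in sim.samples
    ]
    write_table(rows, paths["samples.tsv"])

    paths["probes.tsv"] = out_dir / "probes.tsv"
    with open(paths["probes.tsv"], "w") as fh:
        fh.write("chrom\tpos\n")
        for chrom in sim.genome.names:
            for p in sim.probes[chrom]:
                fh.write(f"{chrom}\t{p}\n")

    paths["genome.tsv"] = out_dir / "genome.tsv"
    with open(paths["genome.tsv"], "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom, length in sim.genome.chroms:
            fh.write(f"{chrom}\t{length}\n")

    for kind, fname in (("gene", "genes.bed"), ("qtl", "qtls.bed")):
        paths[fname] = out_dir / fname
        with open(paths[fname], "w") as fh:
            for f in sim.features:
                if f.kind == kind:
                    fh.write(f"{f.chrom}\t{f.start - 1}\t{f.end}\t{f.name}\n")

    paths["relatedness.tsv"] = out_dir / "relatedness.tsv"
    with open(paths["relatedness.tsv"], "w") as fh:
        fh.write("sample_a\tsample_b\tpi_hat\n")
        for p in sim.relatedness:
            fh.write(f"{p.sample_a}\t{p.sample_b}\t{p.pi_hat}\n")

    paths["truth.tsv"] = out_dir / "truth.tsv"
    with open(paths["truth.tsv"], "w") as fh:
        fh.write("kind\tname\tchrom\tstart\tend\tclass\tcn\tn_carriers\ttrue_freq\n")
        for r in sim.truth.fp_regions:
            fh.write(
                f"fp\t{r.name}\t{r.chrom}\t{r.start}\t{r.end}\t{r.fp_class}\t{r.cn}\t"
                f"{len(r.carriers)}\t\n"
            )
        if sim.truth.diff_region:
            r = sim.truth.diff_region
            freqs = ";".join(f"{k}={v}" for k, v in sorted(r.carrier_prob.items()))
            fh.write(
                f"diff\t{r.name}\t{r.chrom}\t{r.start}\t{r.end}\t{freqs}\t{r.cn}\t"
                f"{len(r.carriers)}\t\n"
            )
        for i, l in enumerate(sim.truth.loci):
            fh.write(
                f"locus\tL{i + 1}\t{l.chrom}\t{l.start}\t{l.end}\t\t{l.cn}\t"
                f"{len(l.carriers)}\t{l.true_freq:.6f}\n"
            )

    paths["config.yaml"] = out_dir / "config.yaml"
    cfg = asdict(config)
    cfg["genome"] = [list(c) for c in config.genome.chroms]
    cfg["planted_fp"] = [asdict(r) for r in config.planted_fp]
    cfg["planted_diff"] = asdict(config.planted_diff) if config.planted_diff else None
    if cfg["planted_diff"]:
        cfg["planted_diff"]["loss_freq"] = dict(cfg["planted_diff"]["loss_freq"])
    cfg["ebv_sex_effect"] = dict(config.ebv_sex_effect)
    paths["config.yaml"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths
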
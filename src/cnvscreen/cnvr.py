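"""CNVR construction and cohort-level summaries.

A CNV region (CNVR) is the union span of overlapping per-sample CNV
calls: the connected components of the >= 1 bp overlap graph on each
chromosome.  Adjacent (bookended) calls do NOT merge — sharing at least
one base pair is the only criterion.  Regions are typed loss, gain or
both from the copy-number direction of their member events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .io import CnvCall, Feature, GenomeLayout, RelatednessPair, SampleMeta, chrom_sort_key

__all__ = [
    "Cnvr",
    "ChromSummary",
    "DEFAULT_QC_THRESHOLDS",
    "qc_filter_samples",
    "relatedness_filter",
    "merge_calls_to_cnvrs",
    "classify_size",
    "chromosome_summaries",
    "overlap_features",
]

DEFAULT_QC_THRESHOLDS: Mapping[str, float] = {
    "lrr_sd": 0.30,
    "baf_drift": 0.01,
    "waviness": 0.05,
}


@dataclass(frozen=True)
class Cnvr:
    """Merged CNV region across samples (1-based closed span)."""

    chrom: str
    start: int
    end: int
    type: str  # loss | gain | both
    n_events: int = 0
    n_samples: int = 0
    member_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("Cnvr start > end")
        if self.type not in ("loss", "gain", "both"):
            raise ValueError(f"bad CNVR type {self.type!r}")
        if self.n_samples > self.n_events:
            raise ValueError("n_samples cannot exceed n_events")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def size_class(self) -> str:
        return classify_size(self)


@dataclass(frozen=True)
class ChromSummary:
    """Per-chromosome CNVR coverage by size class and CNV density."""

    chrom: str
    coverage_pct_total: float
    coverage_pct_large: float
    coverage_pct_medium: float
    coverage_pct_small: float
    cnv_per_mbp: float


def qc_filter_samples(
    samples: Sequence[SampleMeta],
    thresholds: Mapping[str, float] | None = None,
) -> tuple[list[SampleMeta], list[dict]]:
    """Drop samples whose QC metric strictly exceeds its threshold.

    Default thresholds: LRR standard deviation 0.30, BAF drift 0.01,
    waviness factor 0.05.  A sample is excluded iff ANY supplied metric
    exceeds (strict >) its threshold; samples with no QC metrics pass
    with a warning.  Returns (retained, exclusion report).
    """
    thresholds = dict(thresholds) if thresholds is not None else dict(DEFAULT_QC_THRESHOLDS)
    for name, t in thresholds.items():
        if t < 0:
            raise ValueError(f"negative QC threshold for {name}: {t}")
    retained: list[SampleMeta] = []
    report: list[dict] = []
    n_missing = 0
    for s in samples:
        if not s.qc:
            n_missing += 1
            retained.append(s)
            continue
        failures = {
            m: v for m, v in s.qc.items() if m in thresholds and v > thresholds[m]
        }
        if failures:
            report.append({"sample_id": s.sample_id, "failed": failures})
        else:
            retained.append(s)
    if n_missing:
        warnings.warn(
            f"{n_missing} samples lack QC metrics and were retained unchecked",
            stacklevel=2,
        )
    return retained, report


def relatedness_filter(
    samples: Sequence[SampleMeta],
    pairs: Iterable[RelatednessPair],
    cutoff: float = 0.4,
) -> list[SampleMeta]:
    """Greedy pruning of close relatives (pi-hat strictly over ``cutoff``).

    Repeatedly removes the sample participating in the most violating
    pairs (ties broken by lexicographically smallest sample_id) until no
    retained pair exceeds the cutoff.
    """
    ids = {s.sample_id for s in samples}
    adj: dict[str, set[str]] = {}
    for p in pairs:
        for sid in (p.sample_a, p.sample_b):
            if sid not in ids:
                raise ValueError(f"relatedness pair references unknown sample {sid!r}")
        if p.pi_hat > cutoff:
            adj.setdefault(p.sample_a, set()).add(p.sample_b)
            adj.setdefault(p.sample_b, set()).add(p.sample_a)
    removed: set[str] = set()
    while True:
        degrees = {sid: len(nbrs - removed) for sid, nbrs in adj.items() if sid not in removed}
        degrees = {sid: d for sid, d in degrees.items() if d > 0}
        if not degrees:
            break
        worst = min(degrees, key=lambda sid: (-degrees[sid], sid))
        removed.add(worst)
    return [s for s in samples if s.sample_id not in removed]


def merge_calls_to_cnvrs(calls: Sequence[CnvCall]) -> list[Cnvr]:
    """Aggregate overlapping calls into CNVRs (per-chromosome sweep).

    Each CNVR spans min(start)..max(end) of one connected overlap
    component; type is ``both`` iff members include both losses and gains.
    Output is sorted and pairwise non-overlapping per chromosome.
    """
    by_chrom: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    cnvrs: list[Cnvr] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        chunk = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        component: list[CnvCall] = []
        cur_end = -1
        for call in chunk:
            if component and call.start > cur_end:
                cnvrs.append(_component_to_cnvr(chrom, component))
                component = []
                cur_end = -1
            component.append(call)
            cur_end = max(cur_end, call.end)
        if component:
            cnvrs.append(_component_to_cnvr(chrom, component))
    return cnvrs


def _component_to_cnvr(chrom: str, members: list[CnvCall]) -> Cnvr:
    has_loss = any(c.is_loss for c in members)
    has_gain = any(c.is_gain for c in members)
    kind = "both" if has_loss and has_gain else ("loss" if has_loss else "gain")
    return Cnvr(
        chrom=chrom,
        start=min(c.start for c in members),
        end=max(c.end for c in members),
        type=kind,
        n_events=len(members),
        n_samples=len({c.sample_id for c in members}),
        member_ids=tuple(c.sample_id for c in members),
    )


def classify_size(cnvr) -> str:
    """Size class: small < 10 kb <= medium < 100 kb <= large."""
    length = cnvr if isinstance(cnvr, int) else cnvr.length
    if length >= 100_000:
        return "large"
    if length >= 10_000:
        return "medium"
    return "small"


def chromosome_summaries(
    cnvrs: Sequence[Cnvr],
    calls: Sequence[CnvCall],
    genome: GenomeLayout,
) -> list[ChromSummary]:
    """Coverage percentage by CNVR size class and CNV events per Mbp.

    One row per genome chromosome plus an ``ALL`` genome-wide aggregate.
    The total coverage is defined as the sum of the three class
    coverages, so the partition identity holds exactly.
    """
    known = set(genome.names)
    for r in cnvrs:
        if r.chrom not in known:
            raise ValueError(f"CNVR on unknown chromosome {r.chrom!r}")
    for c in calls:
        if c.chrom not in known:
            raise ValueError(f"CNV call on unknown chromosome {c.chrom!r}")

    out: list[ChromSummary] = []
    class_bp_all = {"small": 0, "medium": 0, "large": 0}
    n_calls_all = 0
    for chrom, length in genome.chroms:
        class_bp = {"small": 0, "medium": 0, "large": 0}
        for r in cnvrs:
            if r.chrom == chrom:
                class_bp[classify_size(r)] += r.length
        n_calls = sum(1 for c in calls if c.chrom == chrom)
        out.append(_summary_row(chrom, class_bp, n_calls, length))
        for k in class_bp_all:
            class_bp_all[k] += class_bp[k]
        n_calls_all += n_calls
    out.append(_summary_row("ALL", class_bp_all, n_calls_all, genome.total_length))
    return out


def _summary_row(chrom: str, class_bp: dict, n_calls: int, length: int) -> ChromSummary:
    pct = {k: 100.0 * v / length for k, v in class_bp.items()}
    return ChromSummary(
        chrom=chrom,
        coverage_pct_total=pct["small"] + pct["medium"] + pct["large"],
        coverage_pct_large=pct["large"],
        coverage_pct_medium=pct["medium"],
        coverage_pct_small=pct["small"],
        cnv_per_mbp=n_calls / (length / 1e6),
    )


def overlap_features(intervals: Sequence, features: Sequence[Feature]) -> list[tuple]:
    """All (interval, feature) pairs sharing >= 1 bp on the same chromosome.

    ``intervals`` is any collection of objects with chrom/start/end
    (CNVRs or segments).  Closed coordinates: [100,200] and [201,300]
    do not overlap.
    """
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.chrom, IntervalTree())[f.start : f.end + 1] = f
    pairs: list[tuple] = []
    for iv in intervals:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = sorted(tree[iv.start : iv.end + 1], key=lambda h: (h.begin, h.end, h.data.name))
        for h in hits:
            pairs.append((iv, h.data))
    return pairs
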
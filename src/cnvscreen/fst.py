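"""Multi-allelic F_ST on copy-number states and the two segment screens.

The differentiation statistic treats the six categorical copy-number
states (A0..A4, A>4) of one CNV segment as alleles of a multi-allelic
locus and compares two sample groups X and Y of sizes N_x, N_y with
state-frequency vectors x_i, y_i:

    t_i  = (x_i * N_x + y_i * N_y) / (N_x + N_y)
    H_t  = 1 - sum_i t_i^2
    H_s  = ((1 - sum_i x_i^2) * N_x + (1 - sum_i y_i^2) * N_y) / (N_x + N_y)
    F_ST = (H_t - H_s) / H_t          (0 when H_t = 0)

By convexity H_s <= H_t, so F_ST lies in [0, 1]; it reaches 1 only when
both groups are fixed on different states.

Two screens build on per-segment scans of this statistic:

* the cross-gender screen flags segments whose male/female F_ST betrays
  sex-chromosome sequence misassembled onto an autosome — near-fixed
  female loss for chrY-like regions (F_ST above a high tier) and
  female-enriched gains with low male variant rates for chrX-like
  regions (a moderate tier) — and merges them into false-positive CNVRs;
* the cross-population screen selects the upper tail of the segment
  F_ST distribution between two breeds as lineage-differential CNVRs,
  and the complementary frequency filter defines common CNVRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cnvr import Cnvr, overlap_features
from .segments import (
    NORMAL_STATE,
    Segment,
    SegmentFrequency,
    StateMatrix,
    filter_by_frequency,
    merge_segments_to_cnvrs,
)

__all__ = [
    "FstResult",
    "FpCnvr",
    "ScreenConfig",
    "DifferentialResult",
    "CommonResult",
    "multiallelic_fst",
    "fst_scan",
    "screen_fp_cnvrs",
    "breed_differential",
    "common_cnvrs",
]


@dataclass(frozen=True)
class FstResult:
    """Per-segment F_ST between two groups with the terms of the formula."""

    segment_id: str
    fst: float
    x_freq: tuple[float, ...]
    y_freq: tuple[float, ...]
    n_x: int
    n_y: int
    h_t: float
    h_s: float
    t_vector: tuple[float, ...]


@dataclass(frozen=True)
class FpCnvr:
    """False-positive CNVR: sex-skewed region attributed to misassembly."""

    chrom: str
    start: int
    end: int
    fp_class: str  # Y-like | X-like
    peak_fst: float
    direction: str  # loss_in_female | gain_in_female | loss_in_male | gain_in_male
    n_segments: int
    segment_ids: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the gender and breed screens.

    ``fst_high`` flags chrY-like segments (strict >), ``fst_moderate``
    chrX-like ones (strict >, combined with the female-gain/male-quiet
    pattern bounded by ``male_low_variant``).  ``breed_tail`` is the
    upper-tail mass defining the differential cutoff (nearest-rank
    quantile) unless ``breed_fst_min`` fixes it; the fixed cutoff is
    inclusive (>=).
    """

    fst_high: float = 0.9
    fst_moderate: float = 0.15
    breed_tail: float = 0.005
    breed_fst_min: float | None = None
    male_low_variant: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.fst_moderate <= self.fst_high <= 1:
            raise ValueError("need 0 < fst_moderate <= fst_high <= 1")
        if not 0 < self.breed_tail < 1:
            raise ValueError("breed_tail must be in (0,1)")


def multiallelic_fst(
    x_freq: Sequence[float],
    n_x: int,
    y_freq: Sequence[float],
    n_y: int,
    segment_id: str = "",
) -> FstResult:
    """F_ST between two groups from their state-frequency vectors."""
    x = np.asarray(x_freq, dtype=float)
    y = np.asarray(y_freq, dtype=float)
    if x.shape != y.shape:
        raise ValueError("frequency vectors differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative frequency entries")
    if abs(x.sum() - 1.0) > 1e-9 or abs(y.sum() - 1.0) > 1e-9:
        raise ValueError("frequency vectors must sum to 1")
    if n_x < 1 or n_y < 1:
        raise ValueError("group sizes must be >= 1")
    n = n_x + n_y
    t = (x * n_x + y * n_y) / n
    h_t = 1.0 - float(t @ t)
    h_s = ((1.0 - float(x @ x)) * n_x + (1.0 - float(y @ y)) * n_y) / n
    if h_t <= 0.0:
        fst = 0.0
        h_t = max(h_t, 0.0)
    else:
        fst = (h_t - h_s) / h_t
        fst = min(max(fst, 0.0), 1.0)  # guard float round-off only
    return FstResult(
        segment_id=segment_id,
        fst=fst,
        x_freq=tuple(x),
        y_freq=tuple(y),
        n_x=n_x,
        n_y=n_y,
        h_t=h_t,
        h_s=h_s,
        t_vector=tuple(t),
    )


def fst_scan(
    matrix: StateMatrix,
    group_x: Sequence[str],
    group_y: Sequence[str],
) -> list[FstResult]:
    """Per-segment F_ST between two disjoint sample groups."""
    gx, gy = list(group_x), list(group_y)
    if not gx or not gy:
        raise ValueError("both groups must be nonempty")
    if set(gx) & set(gy):
        raise ValueError("groups must be disjoint")
    rows_x = matrix.rows(gx)
    rows_y = matrix.rows(gy)
    out: list[FstResult] = []
    fx = np.stack([(rows_x == k).mean(axis=0) for k in range(6)], axis=1)
    fy = np.stack([(rows_y == k).mean(axis=0) for k in range(6)], axis=1)
    for g, seg in enumerate(matrix.segments):
        out.append(
            multiallelic_fst(fx[g], len(gx), fy[g], len(gy), segment_id=seg.segment_id)
        )
    return out


def _normalise_cohorts(obj) -> dict:
    if isinstance(obj, Mapping):
        return dict(obj)
    return {"all": obj}


def screen_fp_cnvrs(
    fst_by_sex,
    freqs_by_sex,
    segments: Sequence[Segment],
    config: ScreenConfig = ScreenConfig(),
) -> list[FpCnvr]:
    """Flag and merge segments whose gender skew indicates misassembly.

    ``fst_by_sex`` is a male-vs-female scan (one ``FstResult`` list, or a
    mapping cohort -> list to combine several cohorts by union);
    ``freqs_by_sex`` the matching ``SegmentFrequency`` collections with
    ``female``/``male`` groups.  Tier 1 flags segments with
    F_ST > ``fst_high`` (the chrY pattern); tier 2 those with
    F_ST > ``fst_moderate`` whose female gain frequency exceeds the male
    one while the male variant rate stays under ``male_low_variant`` (the
    chrX pattern).  Flagged segments merge by the adjacency rule; each
    region is classed Y-like when female loss enrichment dominates,
    X-like when female gain enrichment does.
    """
    fst_cohorts = _normalise_cohorts(fst_by_sex)
    freq_cohorts = _normalise_cohorts(freqs_by_sex)
    if set(fst_cohorts) != set(freq_cohorts):
        raise ValueError("fst and frequency cohorts do not match")

    peak_fst: dict[str, float] = {}
    flagged: set[str] = set()
    # per-segment excess of each direction, summed over cohorts
    excess: dict[str, np.ndarray] = {}
    for cohort, results in fst_cohorts.items():
        freqs = {f.segment_id: f for f in freq_cohorts[cohort]}
        for r in results:
            f = freqs.get(r.segment_id)
            if f is None:
                raise KeyError(f"no frequencies for segment {r.segment_id} in cohort {cohort}")
            if "female" not in f.groups or "male" not in f.groups:
                raise ValueError("freqs_by_sex must contain 'female' and 'male' groups")
            fem, mal = f.groups["female"], f.groups["male"]
            peak_fst[r.segment_id] = max(peak_fst.get(r.segment_id, 0.0), r.fst)
            tier1 = r.fst > config.fst_high
            tier2 = (
                r.fst > config.fst_moderate
                and fem.gain_freq > mal.gain_freq
                and mal.variant_freq < config.male_low_variant
            )
            if tier1 or tier2:
                flagged.add(r.segment_id)
            vec = np.array(
                [
                    fem.loss_freq - mal.loss_freq,  # loss_in_female
                    fem.gain_freq - mal.gain_freq,  # gain_in_female
                    mal.loss_freq - fem.loss_freq,  # loss_in_male
                    mal.gain_freq - fem.gain_freq,  # gain_in_male
                ]
            )
            excess[r.segment_id] = excess.get(r.segment_id, np.zeros(4)) + vec

    if not flagged:
        return []
    regions = merge_segments_to_cnvrs(flagged, segments)
    directions = ("loss_in_female", "gain_in_female", "loss_in_male", "gain_in_male")
    out: list[FpCnvr] = []
    for region in regions:
        member_ids = region.member_ids or ()
        total = sum(excess[sid] for sid in member_ids)
        direction = directions[int(np.argmax(total))]
        female_loss = max(total[0], 0.0)
        female_gain = max(total[1], 0.0)
        fp_class = "Y-like" if female_loss >= female_gain else "X-like"
        out.append(
            FpCnvr(
                chrom=region.chrom,
                start=region.start,
                end=region.end,
                fp_class=fp_class,
                peak_fst=max(peak_fst[sid] for sid in member_ids),
                direction=direction,
                n_segments=len(member_ids),
                segment_ids=member_ids,
            )
        )
    return out


def _intersects_fp(region, fp_cnvrs: Sequence[FpCnvr]) -> bool:
    return any(
        fp.chrom == region.chrom and fp.start <= region.end and region.start <= fp.end
        for fp in fp_cnvrs
    )


@dataclass(frozen=True)
class DifferentialResult:
    """Lineage-differential CNVRs with the empirical cutoff used."""

    cnvrs: tuple[Cnvr, ...]
    cutoff: float
    segment_ids: frozenset
    fp_overlap: tuple[bool, ...] = ()


@dataclass(frozen=True)
class CommonResult:
    """CNVRs frequent in every population, with FP intersection flags."""

    cnvrs: tuple[Cnvr, ...]
    segment_ids: frozenset
    fp_overlap: tuple[bool, ...] = ()


def breed_differential(
    fst_by_pop: Sequence[FstResult],
    segments: Sequence[Segment],
    config: ScreenConfig = ScreenConfig(),
    fp_cnvrs: Sequence[FpCnvr] = (),
    matrix: StateMatrix | None = None,
) -> DifferentialResult:
    """Select the upper F_ST tail between two populations and merge it.

    The cutoff is the nearest-rank (1 - ``breed_tail``) quantile of the
    per-segment F_ST distribution unless ``breed_fst_min`` overrides it;
    segments at or above the cutoff merge into differential CNVRs.  Each
    region carries a flag marking intersection with a known
    false-positive CNVR (>= 1 bp).
    """
    values = np.array([r.fst for r in fst_by_pop])
    if values.size == 0:
        raise ValueError("empty F_ST scan")
    if config.breed_fst_min is not None:
        cutoff = float(config.breed_fst_min)
    else:
        # nearest-rank quantile: smallest value with rank >= ceil(q*n)
        rank = int(np.ceil((1.0 - config.breed_tail) * values.size))
        rank = min(max(rank, 1), values.size)
        cutoff = float(np.sort(values)[rank - 1])
    selected = {r.segment_id for r in fst_by_pop if r.fst >= cutoff and r.fst > 0.0}
    cnvrs = merge_segments_to_cnvrs(selected, segments, matrix=matrix) if selected else []
    flags = tuple(_intersects_fp(r, fp_cnvrs) for r in cnvrs)
    return DifferentialResult(tuple(cnvrs), cutoff, frozenset(selected), flags)


def common_cnvrs(
    freqs_by_pop: Sequence[SegmentFrequency],
    segments: Sequence[Segment],
    min_freq: float = 0.05,
    fp_cnvrs: Sequence[FpCnvr] = (),
    matrix: StateMatrix | None = None,
) -> CommonResult:
    """Merge segments frequent (>= ``min_freq``) in every population."""
    if freqs_by_pop and len(next(iter(freqs_by_pop)).groups) < 2:
        raise ValueError("common CNVRs need at least two populations")
    selected = filter_by_frequency(freqs_by_pop, mode="min_all", threshold=min_freq)
    cnvrs = merge_segments_to_cnvrs(selected, segments, matrix=matrix) if selected else []
    flags = tuple(_intersects_fp(r, fp_cnvrs) for r in cnvrs)
    return CommonResult(tuple(cnvrs), frozenset(selected), flags)
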
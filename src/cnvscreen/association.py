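"""Extreme-EBV group construction and the chi-square loss-frequency scan.

Case/control groups are the top and bottom ``n_per_tail`` samples by an
estimated breeding value (EBV).  For each CNV segment, the scan builds
the 2x2 table of loss carriers (state < A2) versus non-carriers across
the two groups and applies Pearson's chi-square test (1 df, no
continuity correction).  Segments significant at ``alpha`` are annotated
with whether they fall inside a known false-positive CNVR — the audit
that exposes sex-misassembly artifacts masquerading as trait
associations when the extreme groups are sex-unbalanced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .fst import FpCnvr
from .io import SampleMeta
from .segments import NORMAL_STATE, StateMatrix

__all__ = ["AssocResult", "ExtremeGroups", "select_extremes", "loss_chisq_scan"]


@dataclass(frozen=True)
class AssocResult:
    """One segment's 2x2 loss-carrier table and chi-square test."""

    segment_id: str
    a: int  # loss in high group
    b: int  # not-loss in high group
    c: int  # loss in low group
    d: int  # not-loss in low group
    chi2: float
    p: float
    significant: bool
    in_fp_cnvr: bool = False


@dataclass(frozen=True)
class ExtremeGroups:
    high: tuple[str, ...]
    low: tuple[str, ...]
    sex_counts: dict  # group -> {sex: count}


def select_extremes(
    samples: Sequence[SampleMeta],
    trait: str,
    n_per_tail: int = 200,
) -> ExtremeGroups:
    """Top and bottom ``n_per_tail`` samples by EBV, with a sex-balance report.

    Samples missing the trait are excluded before ranking (with a
    warning); exact EBV ties at the cut are broken by lexicographic
    sample_id.
    """
    with_trait = [s for s in samples if trait in s.traits]
    if len(with_trait) < len(list(samples)):
        warnings.warn(
            f"{len(list(samples)) - len(with_trait)} samples lack trait {trait!r}; excluded",
            stacklevel=2,
        )
    if not with_trait:
        raise ValueError(f"no samples carry trait {trait!r}")
    if len(with_trait) < 2 * n_per_tail:
        raise ValueError(
            f"need >= {2 * n_per_tail} samples with trait {trait!r}, have {len(with_trait)}"
        )
    by_high = sorted(with_trait, key=lambda s: (-s.traits[trait], s.sample_id))
    by_low = sorted(with_trait, key=lambda s: (s.traits[trait], s.sample_id))
    high = tuple(s.sample_id for s in by_high[:n_per_tail])
    low = tuple(s.sample_id for s in by_low[:n_per_tail])
    meta = {s.sample_id: s for s in with_trait}
    counts = {}
    for name, group in (("high", high), ("low", low)):
        c: dict[str, int] = {}
        for sid in group:
            c[meta[sid].sex] = c.get(meta[sid].sex, 0) + 1
        counts[name] = c
    return ExtremeGroups(high=high, low=low, sex_counts=counts)


def loss_chisq_scan(
    matrix: StateMatrix,
    high: Sequence[str],
    low: Sequence[str],
    alpha: float = 0.01,
    fp_cnvrs: Sequence[FpCnvr] = (),
) -> list[AssocResult]:
    """Pearson chi-square (no continuity correction) on loss carriage.

    Segments with zero loss carriers across both groups are skipped (the
    test is undefined there); segments where everyone is a loss carrier
    get chi2 = 0, p = 1.
    """
    high, low = list(high), list(low)
    if not high or not low:
        raise ValueError("both groups must be nonempty")
    if set(high) & set(low):
        raise ValueError("groups must be disjoint")
    loss_high = (matrix.rows(high) < NORMAL_STATE).sum(axis=0)
    loss_low = (matrix.rows(low) < NORMAL_STATE).sum(axis=0)
    n_high, n_low = len(high), len(low)
    out: list[AssocResult] = []
    for g, seg in enumerate(matrix.segments):
        a, c = int(loss_high[g]), int(loss_low[g])
        b, d = n_high - a, n_low - c
        if a + c == 0:
            continue
        if b + d == 0:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(
                np.array([[a, b], [c, d]]), correction=False
            )
            chi2, p = float(chi2), float(p)
        in_fp = any(
            fp.chrom == seg.chrom and fp.start <= seg.end and seg.start <= fp.end
            for fp in fp_cnvrs
        )
        out.append(
            AssocResult(
                segment_id=seg.segment_id,
                a=a,
                b=b,
                c=c,
                d=d,
                chi2=chi2,
                p=p,
                significant=p < alpha,
                in_fp_cnvr=in_fp,
            )
        )
    return out
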
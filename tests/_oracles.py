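"""Independent brute-force oracles used to validate the implementation.

Everything here recomputes results by the most literal method available
(per-base marking, direct summation, closed forms) and stays independent
of the package's own algorithms.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from cnvscreen.io import CnvCall


def brute_cnvrs(calls, max_pos: int):
    """CNVR spans/types as connected components of the >=1-bp overlap graph.

    Membership is decided per base pair: two calls join one component iff
    some position 1..max_pos lies inside both (so bookended calls stay
    apart).  Components are grown by naive fixed-point iteration.
    """
    by_chrom = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    out = []
    for chrom in sorted(by_chrom):
        chunk = by_chrom[chrom]
        n = len(chunk)
        share = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                lo = max(chunk[i].start, chunk[j].start)
                hi = min(chunk[i].end, chunk[j].end)
                share[i, j] = any(
                    chunk[i].start <= p <= chunk[i].end and chunk[j].start <= p <= chunk[j].end
                    for p in range(lo, hi + 1)
                )
        comp = list(range(n))
        changed = True
        while changed:
            changed = False
            for i in range(n):
                for j in range(n):
                    if share[i, j] and comp[j] != comp[i]:
                        tgt = min(comp[i], comp[j])
                        src = max(comp[i], comp[j])
                        comp = [tgt if c == src else c for c in comp]
                        changed = True
        for label in sorted(set(comp)):
            members = [chunk[i] for i in range(n) if comp[i] == label]
            has_loss = any(c.cn < 2 for c in members)
            has_gain = any(c.cn > 2 for c in members)
            kind = "both" if has_loss and has_gain else ("loss" if has_loss else "gain")
            out.append(
                (chrom, min(c.start for c in members), max(c.end for c in members), kind)
            )
        out.sort(key=lambda t: (t[0], t[1]))
    return out


def brute_segments(calls, max_pos: int):
    """Segments by grouping positions with identical covering-call sets."""
    by_chrom = {}
    for i, c in enumerate(calls):
        by_chrom.setdefault(c.chrom, []).append((i, c))
    out = []
    for chrom in sorted(by_chrom):
        cover = [frozenset() for _ in range(max_pos + 2)]
        for i, c in by_chrom[chrom]:
            for p in range(c.start, c.end + 1):
                cover[p] = cover[p] | {i}
        pos = 1
        while pos <= max_pos:
            if cover[pos]:
                start = pos
                key = cover[pos]
                while pos <= max_pos and cover[pos] == key:
                    pos += 1
                out.append((chrom, start, pos - 1))
            else:
                pos += 1
    return out


def brute_state_matrix(calls, sample_ids, segments):
    """Per-sample state per segment from per-base call lookup at the midpoint.

    Valid because each brute-force segment has a constant covering set.
    """
    states = np.full((len(sample_ids), len(segments)), 2, dtype=int)
    for si, sid in enumerate(sample_ids):
        own = [c for c in calls if c.sample_id == sid]
        for gi, (chrom, start, end) in enumerate(segments):
            mid = (start + end) // 2
            for c in own:
                if c.chrom == chrom and c.start <= mid <= c.end:
                    states[si, gi] = min(c.cn, 5)
                    break
    return states


def fst_direct(x, n_x, y, n_y):
    """Direct plain-float summation of the weighted multi-allelic F_ST."""
    sum_t2 = 0.0
    sum_x2 = 0.0
    sum_y2 = 0.0
    for xi, yi in zip(x, y):
        ti = (xi * n_x + yi * n_y) / (n_x + n_y)
        sum_t2 += ti * ti
        sum_x2 += xi * xi
        sum_y2 += yi * yi
    h_t = 1.0 - sum_t2
    h_s = ((1.0 - sum_x2) * n_x + (1.0 - sum_y2) * n_y) / (n_x + n_y)
    if h_t == 0.0:
        return 0.0
    return (h_t - h_s) / h_t


def fst_biallelic_exact(p: Fraction, q: Fraction) -> Fraction:
    """Exact-rational textbook bi-allelic (H_t - H_s)/H_t at equal group sizes."""
    t = (p + q) / 2
    h_t = 1 - (t**2 + (1 - t) ** 2)
    h_s = (1 - (p**2 + (1 - p) ** 2) + 1 - (q**2 + (1 - q) ** 2)) / 2
    if h_t == 0:
        return Fraction(0)
    return (h_t - h_s) / h_t


def chi2_closed_form(a, b, c, d):
    """2x2 Pearson chi-square: N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def random_instance(rng, max_calls=40, max_samples=20, chrom_len=20_000):
    """Random call set with per-sample non-overlap on one toy chromosome."""
    n_samples = int(rng.integers(1, max_samples + 1))
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    n_calls = int(rng.integers(1, max_calls + 1))
    calls = []
    occupied = {sid: [] for sid in sample_ids}
    for _ in range(n_calls):
        sid = sample_ids[int(rng.integers(n_samples))]
        start = int(rng.integers(1, chrom_len - 100))
        length = int(rng.integers(50, 2_000))
        end = min(start + length - 1, chrom_len)
        if any(start <= e and s <= end for s, e in occupied[sid]):
            continue
        occupied[sid].append((start, end))
        cn = int(rng.choice([0, 1, 1, 3, 3, 4, 6]))
        calls.append(CnvCall(sample_id=sid, chrom="chrT", start=start, end=end, cn=cn))
    return calls, sample_ids
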
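"""CNV segment decomposition, per-sample state assignment and frequencies.

A CNV segment is a maximal interval within which every base pair is
covered by exactly the same set of calls: slicing the call union at all
call starts and (end + 1) positions yields disjoint segments whose
per-sample copy-number state is constant.  Segments are the unit for
frequency and F_ST computation; each sample takes one categorical state
per segment, A0..A4 or A>4 (A2 = normal diploid, the default where no
call covers the segment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cnvr import Cnvr
from .io import CnvCall, ProbeMap, SampleMeta, chrom_sort_key

__all__ = [
    "Segment",
    "StateMatrix",
    "GroupFrequency",
    "SegmentFrequency",
    "STATE_LABELS",
    "decompose_segments",
    "snap_to_probes",
    "assign_states",
    "segment_frequencies",
    "filter_by_frequency",
    "merge_segments_to_cnvrs",
]

#: Categorical copy-number alphabet; index = min(cn, 5), label 5 is ">4".
STATE_LABELS = ("A0", "A1", "A2", "A3", "A4", "A>4")
NORMAL_STATE = 2


def state_index(cn: int) -> int:
    return cn if cn <= 4 else 5


@dataclass(frozen=True)
class Segment:
    """Disjoint genomic slice (1-based closed) with constant covering-call set."""

    segment_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self.segment_id}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _seg(chrom: str, start: int, end: int) -> Segment:
    return Segment(f"{chrom}:{start}-{end}", chrom, start, end)


def decompose_segments(calls: Sequence[CnvCall]) -> list[Segment]:
    """Slice the call union at call boundaries into covered segments.

    Per chromosome, breakpoints {start_j} U {end_j + 1} induce half-open
    slices; only slices covered by at least one call are emitted (as
    closed intervals).  Two base pairs share a segment iff they are
    covered by exactly the same set of calls.
    """
    by_chrom: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    segments: list[Segment] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        chunk = by_chrom[chrom]
        bps = np.unique(
            np.concatenate(
                [
                    np.fromiter((c.start for c in chunk), dtype=np.int64),
                    np.fromiter((c.end + 1 for c in chunk), dtype=np.int64),
                ]
            )
        )
        # coverage delta at each breakpoint -> running coverage per slice
        delta = np.zeros(bps.size, dtype=np.int64)
        starts_idx = np.searchsorted(bps, [c.start for c in chunk])
        ends_idx = np.searchsorted(bps, [c.end + 1 for c in chunk])
        np.add.at(delta, starts_idx, 1)
        np.add.at(delta, ends_idx, -1)
        coverage = np.cumsum(delta)
        for i in range(bps.size - 1):
            if coverage[i] > 0:
                segments.append(_seg(chrom, int(bps[i]), int(bps[i + 1] - 1)))
    return segments


def _nearest_probe(pos: int, probes: np.ndarray, lo_idx: int = 0) -> int | None:
    """Nearest probe position among probes[lo_idx:]; ties to the lower one."""
    cand = probes[lo_idx:]
    if cand.size == 0:
        return None
    i = int(np.searchsorted(cand, pos))
    best = None
    if i > 0:
        best = int(cand[i - 1])
    if i < cand.size:
        right = int(cand[i])
        if best is None or (right - pos) < (pos - best):
            best = right
    return best


def snap_to_probes(
    segments: Sequence[Segment],
    probes: ProbeMap | None,
    return_index: bool = False,
):
    """Snap each segment boundary to the nearest probe position.

    Ties (equidistant probes) resolve to the lower coordinate.  Starts
    are snapped among probes past the previous segment's snapped end so
    the output stays disjoint; segments that become degenerate
    (start > end) are dropped with a warning.  ``probes=None`` (or a
    chromosome absent from the map) leaves segments unchanged.

    With ``return_index`` also returns the positions of the surviving
    segments within the input, so per-segment companions (state-matrix
    columns, frequencies) can be carried through the snapping.
    """
    if probes is None:
        out_id = list(segments)
        return (out_id, list(range(len(out_id)))) if return_index else out_id
    out: list[Segment] = []
    kept: list[int] = []
    prev_end_by_chrom: dict[str, int] = {}
    n_dropped = 0
    for i, seg in enumerate(segments):
        if seg.chrom not in probes:
            out.append(seg)
            kept.append(i)
            continue
        arr = probes[seg.chrom]
        floor = prev_end_by_chrom.get(seg.chrom, 0) + 1
        lo_idx = int(np.searchsorted(arr, floor))
        new_start = _nearest_probe(seg.start, arr, lo_idx)
        new_end = _nearest_probe(seg.end, arr)
        if new_start is None or new_end is None or new_start > new_end:
            n_dropped += 1
            continue
        prev_end_by_chrom[seg.chrom] = new_end
        out.append(_seg(seg.chrom, new_start, new_end))
        kept.append(i)
    if n_dropped:
        warnings.warn(f"{n_dropped} segments degenerate after probe snapping; dropped", stacklevel=2)
    return (out, kept) if return_index else out


class StateMatrix:
    """Samples x segments matrix of categorical copy-number states.

    States are stored as small integers 0..5 (index ``min(cn, 5)``, so 5
    encodes any copy number above four); label via :data:`STATE_LABELS`.
    """

    def __init__(self, samples: Sequence[str], segments: Sequence[Segment], states: np.ndarray):
        self.samples = list(samples)
        self.segments = list(segments)
        states = np.asarray(states, dtype=np.int8)
        if states.shape != (len(self.samples), len(self.segments)):
            raise ValueError("state matrix shape mismatch")
        self.states = states
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}

    @property
    def segment_ids(self) -> list[str]:
        return [s.segment_id for s in self.segments]

    def rows(self, sample_ids: Iterable[str]) -> np.ndarray:
        try:
            idx = [self._sample_idx[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r} in state matrix") from exc
        return self.states[idx, :]

    def label(self, sample_id: str, segment_id: str) -> str:
        g = self.segment_ids.index(segment_id)
        return STATE_LABELS[self.states[self._sample_idx[sample_id], g]]


def assign_states(
    segments: Sequence[Segment],
    calls: Sequence[CnvCall],
    samples: Sequence[SampleMeta] | Sequence[str],
) -> StateMatrix:
    """One categorical state per sample per segment from its unique calls.

    Requires calls of one sample to be pairwise non-overlapping (the
    "unique CNV" precondition); a violation raises naming the sample.
    Segments not covered by a sample's calls default to A2.  Coverage is
    all-or-nothing by construction of :func:`decompose_segments`.
    """
    sample_ids = [s.sample_id if isinstance(s, SampleMeta) else str(s) for s in samples]
    by_sample: dict[str, list[CnvCall]] = {sid: [] for sid in sample_ids}
    for c in calls:
        if c.sample_id in by_sample:
            by_sample[c.sample_id].append(c)
    for sid, chunk in by_sample.items():
        chunk.sort(key=lambda c: (c.chrom, c.start))
        for a, b in zip(chunk, chunk[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ValueError(
                    f"sample {sid!r} has overlapping calls "
                    f"{a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}"
                )

    seg_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g, seg in enumerate(segments):
        seg_by_chrom.setdefault(seg.chrom, []).append((seg.start, g))
    starts_by_chrom = {
        chrom: (np.array([s for s, _ in lst]), [g for _, g in lst])
        for chrom, lst in seg_by_chrom.items()
    }

    states = np.full((len(sample_ids), len(segments)), NORMAL_STATE, dtype=np.int8)
    seg_list = list(segments)
    for si, sid in enumerate(sample_ids):
        for c in by_sample[sid]:
            if c.chrom not in starts_by_chrom:
                continue
            starts, gidx = starts_by_chrom[c.chrom]
            lo = int(np.searchsorted(starts, c.start))
            hi = int(np.searchsorted(starts, c.end, side="right"))
            for k in range(lo, hi):
                g = gidx[k]
                if seg_list[g].end <= c.end:
                    states[si, g] = state_index(c.cn)
    return StateMatrix(sample_ids, seg_list, states)


@dataclass(frozen=True)
class GroupFrequency:
    """State frequencies of one segment within one sample group."""

    n: int
    variant_freq: float
    loss_freq: float
    gain_freq: float
    state_freq: tuple[float, ...]  # over STATE_LABELS


@dataclass(frozen=True)
class SegmentFrequency:
    segment_id: str
    groups: Mapping[str, GroupFrequency]


def segment_frequencies(
    matrix: StateMatrix,
    groups: Mapping[str, Iterable[str]],
) -> list[SegmentFrequency]:
    """Per-group variant/loss/gain and six-state frequencies per segment."""
    group_rows = {}
    for name, members in groups.items():
        members = list(members)
        if not members:
            raise ValueError(f"group {name!r} is empty")
        group_rows[name] = matrix.rows(members)
    out: list[SegmentFrequency] = []
    per_group_counts = {
        name: np.stack([(rows == k).sum(axis=0) for k in range(6)], axis=1)
        for name, rows in group_rows.items()
    }  # each (n_segments, 6)
    for g, seg in enumerate(matrix.segments):
        entry: dict[str, GroupFrequency] = {}
        for name, counts in per_group_counts.items():
            n = int(counts[g].sum())
            freq = counts[g] / n
            loss = float(freq[0] + freq[1])
            gain = float(freq[3] + freq[4] + freq[5])
            entry[name] = GroupFrequency(
                n=n,
                variant_freq=loss + gain,
                loss_freq=loss,
                gain_freq=gain,
                state_freq=tuple(float(f) for f in freq),
            )
        out.append(SegmentFrequency(seg.segment_id, entry))
    return out


def filter_by_frequency(
    freqs: Sequence[SegmentFrequency],
    mode: str,
    threshold: float,
    strict: bool = False,
) -> set[str]:
    """Select segment ids by per-group variant frequency.

    ``min_all`` keeps segments passing the threshold in every group (the
    "common" rule), ``min_any`` if any group passes, ``max_any`` drops a
    segment when any group exceeds the threshold.  ``strict=True`` uses
    strict comparison (e.g. the high-frequency ``> 0.1`` map rule);
    otherwise thresholds are inclusive.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0,1]")
    if mode not in ("min_any", "min_all", "max_any"):
        raise ValueError(f"unknown mode {mode!r}")

    def passes(v: float) -> bool:
        return v > threshold if strict else v >= threshold

    kept: set[str] = set()
    for f in freqs:
        vals = [g.variant_freq for g in f.groups.values()]
        if mode == "min_all" and all(passes(v) for v in vals):
            kept.add(f.segment_id)
        elif mode == "min_any" and any(passes(v) for v in vals):
            kept.add(f.segment_id)
        elif mode == "max_any" and not any(passes(v) for v in vals):
            kept.add(f.segment_id)
    return kept


def merge_segments_to_cnvrs(
    selected_ids: Iterable[str],
    segments: Sequence[Segment],
    matrix: StateMatrix | None = None,
) -> list[Cnvr]:
    """Merge selected segments that overlap or are bookended into regions.

    Adjacent selected segments (next start = previous end + 1) join one
    region.  When a state matrix is supplied the region type is derived
    from the states observed in carriers across member segments;
    otherwise regions are typed from nothing and reported as ``both``.
    """
    selected = set(selected_ids)
    by_id = {s.segment_id: s for s in segments}
    unknown = selected - set(by_id)
    if unknown:
        raise KeyError(f"unknown segment ids: {sorted(unknown)}")
    chosen = sorted(
        (by_id[sid] for sid in selected),
        key=lambda s: (chrom_sort_key(s.chrom), s.start),
    )
    regions: list[list[Segment]] = []
    for seg in chosen:
        if regions and regions[-1][-1].chrom == seg.chrom and seg.start <= regions[-1][-1].end + 1:
            regions[-1].append(seg)
        else:
            regions.append([seg])
    out: list[Cnvr] = []
    for members in regions:
        kind = "both"
        n_events = 0
        n_samples = 0
        if matrix is not None:
            gidx = [matrix.segment_ids.index(m.segment_id) for m in members]
            sub = matrix.states[:, gidx]
            has_loss = bool((sub < NORMAL_STATE).any())
            has_gain = bool((sub > NORMAL_STATE).any())
            kind = "both" if has_loss and has_gain else ("loss" if has_loss else "gain")
            carrier_mask = (sub != NORMAL_STATE).any(axis=1)
            n_samples = int(carrier_mask.sum())
            n_events = n_samples
        out.append(
            Cnvr(
                chrom=members[0].chrom,
                start=members[0].start,
                end=members[-1].end,
                type=kind,
                n_events=n_events,
                n_samples=n_samples,
                member_ids=tuple(m.segment_id for m in members),
            )
        )
    return out
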
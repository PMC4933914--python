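"""High-level composition of the pipeline stages.

These helpers wire the module-level operations together the way a full
analysis runs them: calls -> CNVRs -> segments -> state matrix ->
per-group frequencies -> screens.  The CLI and the reproduction script
are thin layers over this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .cnvr import Cnvr, merge_calls_to_cnvrs
from .fst import (
    FpCnvr,
    FstResult,
    ScreenConfig,
    fst_scan,
    screen_fp_cnvrs,
)
from .io import CnvCall, ProbeMap, SampleMeta
from .segments import (
    Segment,
    SegmentFrequency,
    StateMatrix,
    assign_states,
    decompose_segments,
    segment_frequencies,
    snap_to_probes,
)

__all__ = [
    "sex_groups",
    "population_groups",
    "SegmentedCohort",
    "segment_cohort",
    "gender_screen",
]


def sex_groups(samples: Sequence[SampleMeta]) -> dict[str, list[str]]:
    """Map ``female``/``male`` to sample ids (sex ``unknown`` is left out)."""
    out: dict[str, list[str]] = {}
    for s in samples:
        if s.sex in ("male", "female"):
            out.setdefault(s.sex, []).append(s.sample_id)
    return out


def population_groups(samples: Sequence[SampleMeta]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for s in samples:
        out.setdefault(s.population or "ALL", []).append(s.sample_id)
    return out


@dataclass(frozen=True)
class SegmentedCohort:
    """Calls decomposed into segments with the per-sample state matrix."""

    cnvrs: tuple[Cnvr, ...]
    segments: tuple[Segment, ...]
    matrix: StateMatrix


def segment_cohort(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleMeta],
    probes: ProbeMap | None = None,
) -> SegmentedCohort:
    """CNVR merge + boundary decomposition + state assignment in one step.

    States are assigned on the raw decomposition (where call coverage is
    all-or-nothing) and carried through the probe snapping, which only
    relabels boundaries and may squeeze out sliver segments.
    """
    cnvrs = merge_calls_to_cnvrs(calls)
    raw = decompose_segments(calls)
    matrix = assign_states(raw, calls, samples)
    segments = raw
    if probes is not None:
        segments, kept = snap_to_probes(raw, probes, return_index=True)
        matrix = StateMatrix(matrix.samples, segments, matrix.states[:, kept])
    return SegmentedCohort(tuple(cnvrs), tuple(segments), matrix)


def gender_screen(
    cohort: SegmentedCohort,
    samples: Sequence[SampleMeta],
    config: ScreenConfig = ScreenConfig(),
    split_populations: bool = True,
) -> tuple[dict[str, list[FstResult]], dict[str, list[SegmentFrequency]], list[FpCnvr]]:
    """Male-vs-female F_ST scan per cohort and the misassembly screen.

    With ``split_populations`` the scan runs separately within each
    population and a segment is flagged when it trips a tier in either
    cohort; otherwise one pooled scan is used.
    """
    if split_populations:
        cohorts = population_groups(samples)
        sample_by_id = {s.sample_id: s for s in samples}
        fst_by, freq_by = {}, {}
        for pop, members in cohorts.items():
            sg = sex_groups([sample_by_id[m] for m in members])
            if "male" not in sg or "female" not in sg:
                continue
            fst_by[pop] = fst_scan(cohort.matrix, sg["female"], sg["male"])
            freq_by[pop] = segment_frequencies(cohort.matrix, sg)
    else:
        sg = sex_groups(samples)
        fst_by = {"all": fst_scan(cohort.matrix, sg["female"], sg["male"])}
        freq_by = {"all": segment_frequencies(cohort.matrix, sg)}
    fp = screen_fp_cnvrs(fst_by, freq_by, list(cohort.segments), config)
    return fst_by, freq_by, fp
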
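"""Readers, writers and shared domain records.

All genomic coordinates inside the package are 1-based, closed intervals
(``length = end - start + 1``), matching how SNP-array CNV callers report
the first and last probe of an event.  BED input is the one exception: it
is read as 0-based half-open and converted on the fly.

Chromosome names are matched by exact string after whitespace trimming.
Mismatched naming conventions ("1" vs "chr1") are treated as a data error
by downstream validation rather than silently harmonised.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CnvCall",
    "SampleMeta",
    "GenomeLayout",
    "ProbeMap",
    "Feature",
    "RelatednessPair",
    "CnvParseError",
    "read_cnv_calls",
    "read_sample_table",
    "read_features_bed",
    "read_relatedness",
    "read_genome",
    "read_probe_map",
    "write_table",
    "write_cnv_calls",
    "chrom_sort_key",
]

SEXES = frozenset({"male", "female", "unknown"})


class CnvParseError(ValueError):
    """Raised when an input table violates the format contract."""


def chrom_sort_key(chrom: str) -> tuple:
    """Natural ordering for chromosome names: chr2 < chr10 < chrX."""
    m = re.match(r"^(chr)?(\d+)$", chrom)
    if m:
        return (0, int(m.group(2)), "")
    return (1, 0, chrom)


@dataclass(frozen=True)
class CnvCall:
    """One per-sample CNV event with an integer copy-number state.

    A call is by definition non-normal: ``cn == 2`` is rejected.  Loss
    means ``cn < 2`` (hemizygous or homozygous deletion), gain ``cn > 2``.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    cn: int
    n_probes: int | None = None
    source_line: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"CnvCall {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "start > end"
            )
        if self.start < 1:
            raise ValueError(f"CnvCall start must be >= 1, got {self.start}")
        if self.cn == 2:
            raise ValueError("CnvCall with cn=2 is not a CNV")
        if self.cn < 0:
            raise ValueError(f"copy number must be >= 0, got {self.cn}")
        if self.n_probes is not None and self.n_probes < 1:
            raise ValueError("n_probes must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_loss(self) -> bool:
        return self.cn < 2

    @property
    def is_gain(self) -> bool:
        return self.cn > 2


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: sex, population label, EBV traits and QC metrics."""

    sample_id: str
    sex: str
    population: str | None = None
    traits: Mapping[str, float] = field(default_factory=dict)
    qc: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(
                f"sample {self.sample_id}: sex {self.sex!r} not in {sorted(SEXES)}"
            )
        for k, v in self.traits.items():
            if not np.isfinite(v):
                raise ValueError(f"sample {self.sample_id}: trait {k} not finite")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome layout")
        for c, n in self.chroms:
            if n <= 0:
                raise ValueError(f"chromosome {c} has non-positive length {n}")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    def length(self, chrom: str) -> int:
        for c, n in self.chroms:
            if c == chrom:
                return n
        raise KeyError(chrom)

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.chroms)


@dataclass(frozen=True)
class ProbeMap:
    """Sorted probe positions per chromosome (1-based bp)."""

    positions: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"probe positions on {chrom} not strictly increasing")
            clean[chrom] = arr
        object.__setattr__(self, "positions", clean)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.positions

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.positions[chrom]


@dataclass(frozen=True)
class Feature:
    """Annotated genomic interval (gene or QTL), 1-based closed."""

    chrom: str
    start: int
    end: int
    name: str
    kind: str = "gene"
    attributes: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.name}: start > end")
        if self.kind not in ("gene", "qtl"):
            raise ValueError(f"feature kind must be gene or qtl, got {self.kind!r}")


@dataclass(frozen=True)
class RelatednessPair:
    """Pairwise IBD sharing estimate (pi-hat) between two samples."""

    sample_a: str
    sample_b: str
    pi_hat: float

    def __post_init__(self) -> None:
        if self.sample_a == self.sample_b:
            raise ValueError(f"self-pair for sample {self.sample_a}")
        if not 0.0 <= self.pi_hat <= 1.0:
            raise ValueError(f"pi_hat {self.pi_hat} outside [0,1]")


# ---------------------------------------------------------------------------
# readers

_PENN_REGION = re.compile(r"^(?P<chrom>[^:]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")
_PENN_STATE = re.compile(r"^state\d+,cn=(?P<cn>\d+)$")


def _parse_penncnv_line(line: str, lineno: int) -> CnvCall:
    fields_ = line.split()
    if len(fields_) < 5:
        raise CnvParseError(f"line {lineno}: expected >= 5 whitespace fields")
    m = _PENN_REGION.match(fields_[0])
    if not m:
        raise CnvParseError(f"line {lineno}: malformed region token {fields_[0]!r}")
    cn = None
    n_probes = None
    for tok in fields_[1:4]:
        sm = _PENN_STATE.match(tok)
        if sm:
            cn = int(sm.group("cn"))
        elif tok.startswith("numsnp="):
            try:
                n_probes = int(tok.split("=", 1)[1])
            except ValueError as exc:
                raise CnvParseError(f"line {lineno}: bad numsnp token {tok!r}") from exc
    if cn is None:
        raise CnvParseError(f"line {lineno}: missing state/cn token")
    sample = fields_[4]
    try:
        return CnvCall(
            sample_id=sample,
            chrom=m.group("chrom").strip(),
            start=int(m.group("start").replace(",", "")),
            end=int(m.group("end").replace(",", "")),
            cn=cn,
            n_probes=n_probes,
            source_line=f"line {lineno}",
        )
    except ValueError as exc:
        raise CnvParseError(f"line {lineno}: {exc}") from exc


def read_cnv_calls(path: str | Path, dialect: str = "tsv") -> list[CnvCall]:
    """Read per-sample CNV calls.

    ``dialect="penncnv"`` parses the rawcnv text dialect
    (``chrN:start-end numsnp=K length=L stateS,cn=C <sample> ...``);
    ``dialect="tsv"`` a headered table with columns
    sample_id, chrom, start, end, cn (optionally n_probes).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "penncnv":
        calls = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                calls.append(_parse_penncnv_line(line, lineno))
        return calls
    if dialect == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
        except pd.errors.EmptyDataError:
            return []
        required = {"sample_id", "chrom", "start", "end", "cn"}
        missing = required - set(df.columns)
        if missing:
            raise CnvParseError(f"missing columns: {sorted(missing)}")
        calls = []
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                n_probes = None
                if "n_probes" in df.columns and pd.notna(getattr(row, "n_probes")):
                    n_probes = int(getattr(row, "n_probes"))
                calls.append(
                    CnvCall(
                        sample_id=str(row.sample_id),
                        chrom=str(row.chrom).strip(),
                        start=int(row.start),
                        end=int(row.end),
                        cn=int(row.cn),
                        n_probes=n_probes,
                        source_line=f"line {i}",
                    )
                )
            except (ValueError, TypeError) as exc:
                raise CnvParseError(f"line {i}: {exc}") from exc
        return calls
    raise ValueError(f"unknown dialect {dialect!r}; expected 'penncnv' or 'tsv'")


_QC_COLUMNS = {"qc_lrr_sd": "lrr_sd", "qc_baf_drift": "baf_drift", "qc_waviness": "waviness"}


def read_sample_table(path: str | Path) -> list[SampleMeta]:
    """Read the sample metadata TSV (sample_id, sex[, population, qc_*, traits...])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "sex" not in df.columns:
        raise CnvParseError("sample table needs at least sample_id and sex columns")
    dupes = df["sample_id"][df["sample_id"].duplicated()]
    if not dupes.empty:
        raise CnvParseError(f"duplicate sample_id: {sorted(set(dupes))}")
    trait_cols = [
        c
        for c in df.columns
        if c not in ("sample_id", "sex", "population") and c not in _QC_COLUMNS
    ]
    samples = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        qc = {
            short: float(d[col])
            for col, short in _QC_COLUMNS.items()
            if col in d and pd.notna(d[col])
        }
        traits = {c: float(d[c]) for c in trait_cols if pd.notna(d[c])}
        samples.append(
            SampleMeta(
                sample_id=str(d["sample_id"]),
                sex=str(d["sex"]).strip().lower(),
                population=str(d["population"]).strip() if "population" in d and pd.notna(d["population"]) else None,
                traits=traits,
                qc=qc or None,
            )
        )
    return samples


def read_features_bed(path: str | Path, kind: str = "gene") -> list[Feature]:
    """Read a BED3+name file, converting 0-based half-open to 1-based closed."""
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise CnvParseError(f"line {lineno}: BED needs >= 3 columns")
            try:
                bed_start, bed_end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise CnvParseError(f"line {lineno}: non-integer coordinates") from exc
            if bed_end <= bed_start:
                raise CnvParseError(f"line {lineno}: BED end <= start")
            name = cols[3] if len(cols) > 3 and cols[3] else f"{kind}_{lineno}"
            attributes = None
            if kind == "qtl" and len(cols) > 4 and cols[4]:
                attributes = {"trait": cols[4]}
            feats.append(
                Feature(
                    chrom=cols[0].strip(),
                    start=bed_start + 1,
                    end=bed_end,
                    name=name,
                    kind=kind,
                    attributes=attributes,
                )
            )
    return feats


def read_relatedness(path: str | Path) -> list[RelatednessPair]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_a": str, "sample_b": str})
    return [
        RelatednessPair(str(r.sample_a), str(r.sample_b), float(r.pi_hat))
        for r in df.itertuples(index=False)
    ]


def read_genome(path: str | Path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GenomeLayout(tuple((str(r.chrom).strip(), int(r.length)) for r in df.itertuples(index=False)))


def read_probe_map(path: str | Path) -> ProbeMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    pos = {
        str(chrom): np.sort(sub["pos"].to_numpy(dtype=np.int64))
        for chrom, sub in df.groupby("chrom", sort=True)
    }
    return ProbeMap(pos)


# ---------------------------------------------------------------------------
# writers


def _record_to_dict(rec) -> dict:
    if isinstance(rec, dict):
        return dict(rec)
    out = {}
    for f in fields(rec):
        v = getattr(rec, f.name)
        if f.name in ("source_line", "attributes", "member_ids"):
            continue
        if isinstance(v, Mapping):
            for k, vv in v.items():
                out[f"{f.name}_{k}"] = vv
        elif isinstance(v, np.ndarray):
            for i, vv in enumerate(v):
                out[f"{f.name}_{i}"] = vv
        else:
            out[f.name] = v
    return out


def write_table(
    records: Iterable,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write a homogeneous record collection as a headered TSV.

    Rows are sorted genomically when chrom/start columns are present;
    floats are written at 6 decimals.  An empty collection needs an
    explicit ``columns`` to produce the header-only file.
    """
    records = list(records)
    if records:
        df = pd.DataFrame([_record_to_dict(r) for r in records])
        if columns is not None:
            df = df[list(columns)]
    else:
        if columns is None:
            raise ValueError("columns required to write an empty table")
        df = pd.DataFrame(columns=list(columns))
    sort_cols = [c for c in ("chrom", "start", "end", "sample_id", "segment_id") if c in df.columns]
    if "chrom" in df.columns and not df.empty:
        df = df.assign(_k=df["chrom"].map(chrom_sort_key)).sort_values(
            ["_k"] + [c for c in sort_cols if c != "chrom"], kind="mergesort"
        ).drop(columns="_k")
    elif sort_cols and not df.empty:
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_cnv_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    """Write calls in the generic TSV dialect (round-trips with read_cnv_calls)."""
    write_table(
        calls,
        path,
        columns=["sample_id", "chrom", "start", "end", "cn", "n_probes"],
    )


def warn_missing_qc(samples: Iterable[SampleMeta]) -> list[str]:
    """Emit one warning naming samples that carry no QC metrics; return their ids."""
    missing = [s.sample_id for s in samples if not s.qc]
    if missing:
        warnings.warn(
            f"{len(missing)} samples have no QC metrics and pass QC by default",
            stacklevel=2,
        )
    return missing
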
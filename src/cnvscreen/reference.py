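"""Bundled reference coordinates for validated misassembly artifacts.

Nine false-positive CNVRs on the cattle UMD3.1 assembly whose sequence
maps back to chrY, chrX or unplaced scaffolds of Btau_4.6.1 — autosomal
regions that recurrently produce sex-skewed CNV calls because sex-
chromosome sequence was scaffolded onto autosomes.  Shipped as a small
curated table so interval arithmetic over a validated artifact set can
be exercised without cohort genotypes.

The worked-example deletion on chr5 (58,386,640-58,441,130, ~54 kb)
enriched in indicine cattle is exposed as a module constant.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_fp_reference", "CHR5_DELETION"]

#: The indicine-enriched chr5 deletion region (chrom, start, end), 1-based closed.
CHR5_DELETION = ("chr5", 58_386_640, 58_441_130)


def load_fp_reference() -> pd.DataFrame:
    """Reference FP-CNVR table with a derived ``length`` column (bp).

    Columns: name, chrom, start, end, source_chrom (where the sequence
    actually belongs: chrY, chrX or chrUn), genes, qtl_count, length.
    Y-chromosome-derived regions present as near-fixed loss in females;
    X/unplaced ones as female-enriched gains.
    """
    with resources.files("cnvscreen.data").joinpath("fp_cnvr_reference.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["genes"] = df["genes"].fillna("")
    df["length"] = df["end"] - df["start"] + 1
    return df
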
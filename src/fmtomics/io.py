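"""TSV readers/writers for the pipeline's tabular artifacts."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .metabolome import MetaboliteMatrix
from .prep import CountTable, SampleMeta


def read_count_table(counts_path, taxonomy_path=None) -> CountTable:
    """Read a samples x features TSV count table (first column = sample id)
    and an optional taxonomy TSV (first column = feature id, rank columns;
    a single semicolon-delimited ``lineage`` column is also accepted)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    tax = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
        if list(tax.columns) == ["lineage"]:
            from .prep import RANKS

            parts = tax["lineage"].str.split(";", expand=True)
            parts.columns = list(RANKS[: parts.shape[1]])
            tax = parts.apply(lambda c: c.str.strip())
    return CountTable(counts.astype(int), tax)


def read_metadata(path) -> SampleMeta:
    tbl = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMeta(tbl)


def read_metabolites(path, anchors_path=None) -> MetaboliteMatrix:
    """Read a metabolite TSV whose first data column is the per-sample
    ``batch`` label, plus an optional two-column anchor-pair TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    batch = df["batch"]
    vals = df.drop(columns=["batch"]).astype(float)
    pairs = []
    if anchors_path is not None and Path(anchors_path).exists():
        ap = pd.read_csv(anchors_path, sep="\t")
        pairs = list(zip(ap.iloc[:, 0], ap.iloc[:, 1]))
    return MetaboliteMatrix(intensities=vals, batch=batch, anchor_pairs=pairs)
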
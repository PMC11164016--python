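"""Sample/feature filtering and timepoint selection for ASV count tables.

The preprocessing contract applied to 16S amplicon count tables before any
downstream statistics, in this order:

1. :func:`filter_samples` — drop shallow samples (total reads <= ``min_reads``,
   i.e. strictly-greater-than retention).
2. :func:`filter_asvs` — keep ASVs exceeding a within-sample relative-abundance
   threshold in at least ``min_samples`` samples.
3. :func:`collapse_to_genus` — sum member ASVs per genus and apply a
   prevalence filter; ASVs without a genus assignment are promoted to their
   best assigned higher rank (e.g. ``"Lachnospiraceae Family"``).
4. :func:`select_analysis_sample` — pick one "early post" sample per patient
   (day-28 if available, else day-10).

Total counts never increase at any stage, and the genus collapse conserves
per-sample totals of taxonomically assigned ASVs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

TIMEPOINTS = ("baseline", "pre", "post10", "post28", "late")
EARLY_POST = "early_post"

# taxonomy ranks, coarsest first; "genus" must be last
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


@dataclass
class CountTable:
    """Samples x features nonnegative integer count matrix.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are samples, columns are features (ASVs or genera). Values are
        nonnegative integers.
    taxonomy : pandas.DataFrame, optional
        Indexed by feature id with rank columns (subset of
        ``("kingdom", ..., "genus")``). Required for genus collapse.
    """

    counts: pd.DataFrame
    taxonomy: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate feature ids in count table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.taxonomy is not None:
            extra = self.taxonomy.index.difference(self.counts.columns)
            if len(extra):
                # taxonomy may only describe features present in the table
                self.taxonomy = self.taxonomy.drop(index=extra)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list:
        return list(self.counts.columns)

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1; all-zero rows stay 0)."""
        tot = self.counts.sum(axis=1).replace(0, np.nan)
        return self.counts.div(tot, axis=0).fillna(0.0)


@dataclass
class SampleMeta:
    """Per-sample clinical/design annotations.

    ``table`` is indexed by sample id with columns: ``patient_id``, ``role``
    ({patient, donor}), ``arm`` ({FMT, placebo, NA}), ``timepoint``,
    ``donor_id`` (nullable), ``outcome`` ({0, 1, NA}; grade II-IV aGVHD),
    ``prophylaxis`` ({PTCy, other}).
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        pats = self.table[self.table["role"] == "patient"] if len(self.table) else self.table
        if len(pats):
            dup = pats.duplicated(subset=["patient_id", "timepoint"])
            if dup.any():
                raise ValueError(
                    "multiple samples for one (patient, timepoint): "
                    + ", ".join(pats.index[dup][:5])
                )

    def patients(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "patient"]

    def donors(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "donor"]


def filter_samples(t: CountTable, min_reads: int = 1000) -> CountTable:
    """Retain samples with total reads strictly greater than ``min_reads``."""
    keep = t.counts.sum(axis=1) > min_reads
    if not keep.any():
        warnings.warn(
            f"filter_samples removed every sample (min_reads={min_reads})",
            stacklevel=2,
        )
    return CountTable(t.counts.loc[keep], t.taxonomy)


def filter_asvs(
    t: CountTable, min_rel: float = 0.001, min_samples: int = 2
) -> CountTable:
    """Keep features whose relative abundance exceeds ``min_rel`` in at least
    ``min_samples`` samples.

    Relative abundances are computed per sample on the table as given, so this
    should be run after :func:`filter_samples`.
    """
    if t.counts.shape[0] < min_samples:
        raise ValueError(
            f"need at least {min_samples} samples, have {t.counts.shape[0]}"
        )
    rel = t.relative()
    keep = (rel > min_rel).sum(axis=0) >= min_samples
    kept = t.counts.loc[:, keep]
    tax = t.taxonomy.loc[t.taxonomy.index.intersection(kept.columns)] if t.taxonomy is not None else None
    return CountTable(kept, tax)


def _genus_label(row: pd.Series) -> str:
    """Genus label for one taxonomy row; unassigned genera promote to the
    best assigned higher rank, tagged with that rank's name."""
    g = row.get("genus")
    if isinstance(g, str) and g.strip():
        return g
    for rank in reversed(RANKS[:-1]):
        v = row.get(rank)
        if isinstance(v, str) and v.strip():
            return f"{v} {rank.capitalize()}"
    return "Unassigned"


def collapse_to_genus(t: CountTable, prevalence_min: float = 0.01) -> CountTable:
    """Sum ASV counts within genus; keep genera present (count > 0) in at
    least ``ceil(prevalence_min * n_samples)`` samples."""
    if t.taxonomy is None:
        raise ValueError("taxonomy required for genus collapse")
    missing = t.counts.columns.difference(t.taxonomy.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} features lack taxonomy rows (e.g. {missing[0]!r})"
        )
    labels = t.taxonomy.loc[t.counts.columns].apply(_genus_label, axis=1)
    genus = t.counts.T.groupby(labels.to_numpy()).sum().T
    genus = genus.sort_index(axis=1)
    n = genus.shape[0]
    need = math.ceil(prevalence_min * n)
    keep = (genus > 0).sum(axis=0) >= need
    return CountTable(genus.loc[:, keep], None)


def select_analysis_sample(meta: SampleMeta) -> SampleMeta:
    """One early-post sample per patient: day-28 if present, else day-10.

    Returns a new metadata table in which the chosen rows carry timepoint
    ``"early_post"``; all other timepoints are passed through unchanged.
    """
    tbl = meta.table.copy()
    pats = tbl[(tbl["role"] == "patient") & tbl["timepoint"].isin(["post10", "post28"])]
    chosen = []
    for _, grp in pats.groupby("patient_id", sort=False):
        tp = "post28" if (grp["timepoint"] == "post28").any() else "post10"
        chosen.append(grp[grp["timepoint"] == tp].index[0])
    keep = tbl["timepoint"].isin(["post10", "post28"])
    tbl = tbl[~keep | tbl.index.isin(chosen)].copy()
    tbl.loc[tbl.index.isin(chosen), "timepoint"] = EARLY_POST
    return SampleMeta(tbl)


def prepare_counts(
    t: CountTable,
    min_reads: int = 1000,
    min_rel: float = 0.001,
    min_samples: int = 2,
    prevalence_min: float = 0.01,
) -> tuple[CountTable, CountTable]:
    """Full filtering cascade; returns ``(filtered ASV table, genus table)``."""
    s = filter_samples(t, min_reads)
    a = filter_asvs(s, min_rel, min_samples)
    g = collapse_to_genus(a, prevalence_min)
    return a, g
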
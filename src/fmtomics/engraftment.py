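"""Donor engraftment quantification via shared-ASV presence similarity.

Within one genus, the ASV-level presence sets of a recipient's early
post-FMT sample and of the assigned donor's sample are compared with a
binary similarity index (Jaccard by default: shared ASVs over the union,
ignoring joint absences). Across FMT-arm patients the similarity is then
correlated (Spearman) with the genus's post-FMT relative abundance and with
its pre-to-post abundance change — high correlation indicates that the
post-FMT expansion of the genus is carried by donor-derived variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .prep import CountTable, SampleMeta, EARLY_POST


def binary_similarity(sample_asvs, donor_asvs, method: str = "jaccard") -> float:
    """Presence/absence similarity between two ASV sets.

    ``jaccard``: |A & B| / |A | B| (both empty -> 0 with a warning);
    ``dice``: 2|A & B| / (|A| + |B|); ``simple_matching`` requires the
    universe and is offered through :func:`engraftment_analysis` only.
    """
    a, b = set(sample_asvs), set(donor_asvs)
    if not a and not b:
        warnings.warn("both ASV sets empty; similarity set to 0", stacklevel=2)
        return 0.0
    inter = len(a & b)
    if method == "jaccard":
        return inter / len(a | b)
    if method == "dice":
        return 2 * inter / (len(a) + len(b))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class EngraftmentRecord:
    patient_id: str
    donor_id: str
    genus: str
    similarity: float
    post_abundance: float
    pre_abundance: float
    abundance_change: float


def _genus_asvs(t: CountTable, genus: str) -> list[str]:
    if t.taxonomy is None:
        raise ValueError("ASV table needs taxonomy to restrict to a genus")
    tax = t.taxonomy
    hit = tax.index[(tax.get("genus") == genus)]
    if not len(hit):
        raise ValueError(f"no ASVs assigned to genus {genus!r}")
    return [a for a in hit if a in t.counts.columns]


def engraftment_analysis(
    counts: CountTable,
    meta: SampleMeta,
    genus: str,
    method: str = "jaccard",
    presence_min_count: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Per-patient donor similarity and genus abundance for the FMT arm.

    Eligible patients are FMT-arm patients with an early-post sample and an
    assigned donor whose sample is in the table. Returns the per-patient
    record table and a summary with Spearman rho/p against post-FMT
    abundance and against the pre-to-post abundance change.
    """
    asvs = _genus_asvs(counts, genus)
    tbl = meta.table
    rel = counts.relative()
    donors = tbl[tbl["role"] == "donor"]
    donor_sample = {row["patient_id"]: sid for sid, row in donors.iterrows()}
    # donor metadata rows use patient_id to carry the donor's own id
    records = []
    pats = tbl[(tbl["role"] == "patient") & (tbl["arm"] == "FMT")]
    for pid, grp in pats.groupby("patient_id", sort=False):
        early = grp[grp["timepoint"] == EARLY_POST]
        if early.empty:
            continue
        sid = early.index[0]
        if sid not in counts.counts.index:
            continue
        did = early["donor_id"].iloc[0]
        dsid = donor_sample.get(did)
        if dsid is None or dsid not in counts.counts.index:
            continue
        sample_set = [a for a in asvs if counts.counts.loc[sid, a] >= presence_min_count]
        donor_set = [a for a in asvs if counts.counts.loc[dsid, a] >= presence_min_count]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = binary_similarity(sample_set, donor_set, method=method)
        post_ab = float(rel.loc[sid, asvs].sum())
        pre_rows = grp[grp["timepoint"] == "pre"]
        pre_ab = (
            float(rel.loc[pre_rows.index[0], asvs].sum())
            if len(pre_rows) and pre_rows.index[0] in rel.index
            else np.nan
        )
        records.append(
            EngraftmentRecord(
                patient_id=pid,
                donor_id=did,
                genus=genus,
                similarity=sim,
                post_abundance=post_ab,
                pre_abundance=pre_ab,
                abundance_change=post_ab - pre_ab if np.isfinite(pre_ab) else np.nan,
            )
        )
    if not records:
        raise ValueError("no eligible FMT-arm patients with donor samples")
    df = pd.DataFrame([r.__dict__ for r in records]).set_index("patient_id")
    if len(df) < 2:
        raise ValueError("Spearman correlation undefined for a single patient")
    rho_post, p_post = stats.spearmanr(df["similarity"], df["post_abundance"])
    chg = df.dropna(subset=["abundance_change"])
    if len(chg) >= 2:
        rho_chg, p_chg = stats.spearmanr(chg["similarity"], chg["abundance_change"])
    else:
        rho_chg, p_chg = np.nan, np.nan
    summary = {
        "genus": genus,
        "n": int(len(df)),
        "rho_post_abundance": float(rho_post),
        "p_post_abundance": float(p_post),
        "rho_abundance_change": float(rho_chg),
        "p_abundance_change": float(p_chg),
    }
    return df, summary
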
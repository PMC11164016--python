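"""Cross-compartment correlation mapping between taxa/clusters and metabolites.

Rows are the union of each topic's top taxa (as clr-transformed genus
abundances) and the topic proportions themselves; columns are the
highest-variance metabolites plus any pinned ids (e.g. an outcome-associated
metabolite). Cells are Spearman rho with a two-sided p, masked at an
unadjusted alpha — a hypothesis-generating map, not a corrected test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .compositions import clr_transform
from .topics import TopicModelResult, top_taxa


@dataclass
class CrossCorrelationMap:
    rho: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame  # True where p < alpha
    alpha: float
    n_pairs: int


def select_features(
    topics: TopicModelResult,
    genus_table: pd.DataFrame,
    metab: pd.DataFrame,
    n_taxa: int = 5,
    n_metab: int = 50,
    pinned_taxa=(),
    pinned_metabolites=(),
) -> tuple[list[str], list[str]]:
    """Feature lists for the correlation map.

    Taxa: deduplicated union of each topic's top ``n_taxa`` genera plus
    pinned ids (each must exist in ``genus_table``). Metabolites: the
    ``n_metab`` with the highest variance of log values plus pinned ids.
    """
    per_topic = top_taxa(topics, n=n_taxa)
    taxa: list[str] = []
    for lst in per_topic.values():
        for g in lst:
            if g not in taxa:
                taxa.append(g)
    for g in pinned_taxa:
        if g not in genus_table.columns:
            raise ValueError(f"pinned taxon {g!r} not in genus table")
        if g not in taxa:
            taxa.append(g)
    vals = metab.to_numpy(dtype=float)
    if (vals < 0).any():
        # already on a log (or standardized) scale
        logv = vals
    elif (vals == 0).any():
        logv = np.log(vals + vals[vals > 0].min() / 2)
    else:
        logv = np.log(vals)
    var = pd.Series(np.var(logv, axis=0, ddof=1), index=metab.columns)
    mets = list(var.sort_values(ascending=False).index[:n_metab])
    for mid in pinned_metabolites:
        if mid not in metab.columns:
            raise ValueError(f"pinned metabolite {mid!r} not in metabolite matrix")
        if mid not in mets:
            mets.append(mid)
    return taxa, mets


def cross_correlate(
    rows: pd.DataFrame, cols: pd.DataFrame, alpha: float = 0.05
) -> CrossCorrelationMap:
    """Pairwise Spearman rho and two-sided p between row features and column
    features over shared samples (inner-joined on index).

    Constant features give rho = NaN and are masked out.
    """
    shared = rows.index.intersection(cols.index)
    if len(shared) < 3:
        raise ValueError(f"need at least 3 paired samples, have {len(shared)}")
    a = rows.loc[shared]
    b = cols.loc[shared]
    nr, nc = a.shape[1], b.shape[1]
    rho = np.full((nr, nc), np.nan)
    pval = np.full((nr, nc), np.nan)
    for i in range(nr):
        x = a.iloc[:, i].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        for j in range(nc):
            yv = b.iloc[:, j].to_numpy(dtype=float)
            if np.ptp(yv) == 0:
                continue
            r, p = stats.spearmanr(x, yv)
            rho[i, j], pval[i, j] = r, p
    rho_df = pd.DataFrame(rho, index=a.columns, columns=b.columns)
    p_df = pd.DataFrame(pval, index=a.columns, columns=b.columns)
    mask = (p_df < alpha).fillna(False)
    return CrossCorrelationMap(rho=rho_df, p=p_df, mask=mask, alpha=alpha, n_pairs=len(shared))


def taxa_cluster_features(
    genus_table: pd.DataFrame,
    topics: TopicModelResult,
    taxa: list[str],
    pseudocount: float = 0.5,
    topic_floor: float = 1e-6,
    clr_taxa: bool = True,
) -> pd.DataFrame:
    """Row-feature matrix: clr genus abundances for ``taxa`` joined with the
    topic proportions (floored against exact zeros)."""
    if clr_taxa:
        g = clr_transform(genus_table, pseudocount)[taxa]
    else:
        tot = genus_table.sum(axis=1)
        g = genus_table.div(tot, axis=0)[taxa]
    t = topics.sample_topics.clip(lower=topic_floor)
    t = t.div(t.sum(axis=1), axis=0)
    t = t.loc[t.index.intersection(g.index)]
    return g.join(t, how="inner")
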
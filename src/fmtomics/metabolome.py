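"""Batch normalization and QC for untargeted serum metabolomics.

The pipeline, in order: anchor-ratio batch adjustment (a set of identical
samples run in both LC-MS batches gives per-metabolite reference/target
ratios; the median ratio rescales the target batch), a detection filter
(drop metabolites undetected in more than a fraction of samples),
collinearity pruning (one representative per connected component of the
Spearman rho > threshold graph), half-minimum imputation of remaining
non-detections, and log transform with optional per-metabolite
standardization. Zero intensity means "not detected" throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

REFERENCE = "reference"
TARGET = "target"


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites nonnegative intensity matrix with batch labels.

    ``anchor_pairs`` lists (reference sample id, target sample id) pairs that
    are the same physical sample run in both batches.
    """

    intensities: pd.DataFrame
    batch: pd.Series
    anchor_pairs: list[tuple[str, str]] = field(default_factory=list)
    pathway: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be nonnegative")
        self.batch = self.batch.reindex(self.intensities.index)
        if self.batch.isna().any():
            raise ValueError("every sample needs a batch label")
        bad = set(self.batch.unique()) - {REFERENCE, TARGET}
        if bad:
            raise ValueError(f"unknown batch labels {bad}")
        for ref, tgt in self.anchor_pairs:
            if ref not in self.intensities.index or tgt not in self.intensities.index:
                raise ValueError(f"anchor pair ({ref}, {tgt}) references missing samples")
            if self.batch[ref] != REFERENCE or self.batch[tgt] != TARGET:
                raise ValueError(f"anchor pair ({ref}, {tgt}) has wrong batch labels")

    def copy_with(self, intensities: pd.DataFrame) -> "MetaboliteMatrix":
        keep = intensities.columns
        pw = self.pathway.reindex(keep) if self.pathway is not None else None
        return MetaboliteMatrix(
            intensities=intensities,
            batch=self.batch.reindex(intensities.index),
            anchor_pairs=[
                (r, t) for r, t in self.anchor_pairs
                if r in intensities.index and t in intensities.index
            ],
            pathway=pw,
        )


def batch_adjust(m: MetaboliteMatrix, mode: str = "per-metabolite") -> MetaboliteMatrix:
    """Rescale the target batch by the median anchor ratio.

    For each metabolite, factor = median over anchor pairs of
    (reference value / target value), excluding pairs where either value is
    a non-detection; target-batch values are multiplied by the factor (zeros
    stay zero). Metabolites with fewer than 3 clean anchor pairs fall back to
    the global median factor; ``mode="global"`` applies the global factor to
    every metabolite.
    """
    if not m.anchor_pairs:
        raise ValueError("batch adjustment requires anchor pairs")
    vals = m.intensities
    ref_ids = [r for r, _ in m.anchor_pairs]
    tgt_ids = [t for _, t in m.anchor_pairs]
    x = vals.loc[ref_ids].to_numpy(dtype=float)  # anchors x metabolites
    y = vals.loc[tgt_ids].to_numpy(dtype=float)
    clean = (x > 0) & (y > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(clean, x / np.where(y > 0, y, 1.0), np.nan)
    if not clean.any():
        raise ValueError("no anchor pair with both values detected for any metabolite")
    global_factor = float(np.nanmedian(ratios))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        per_met = np.nanmedian(ratios, axis=0)
    n_clean = clean.sum(axis=0)
    if mode == "global":
        factors = np.full(vals.shape[1], global_factor)
    elif mode == "per-metabolite":
        fallback = n_clean < 3
        if fallback.any():
            log.info(
                "batch_adjust: %d metabolite(s) with <3 clean anchor pairs use "
                "the global median factor %.4g", int(fallback.sum()), global_factor,
            )
        factors = np.where(fallback, global_factor, per_met)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = vals.copy()
    is_target = (m.batch == TARGET).to_numpy()
    out.iloc[is_target] = out.iloc[is_target].to_numpy() * factors[None, :]
    return m.copy_with(out)


def detection_filter(m: MetaboliteMatrix, max_undetected: float = 0.25) -> MetaboliteMatrix:
    """Drop metabolites whose non-detection (zero) rate is strictly greater
    than ``max_undetected``."""
    zero_rate = (m.intensities == 0).mean(axis=0)
    keep = zero_rate <= max_undetected
    return m.copy_with(m.intensities.loc[:, keep])


def _spearman_matrix(vals: np.ndarray) -> np.ndarray:
    """Pairwise Spearman rho with average ranks; constant columns get rho 0."""
    n, p = vals.shape
    ranks = np.apply_along_axis(stats.rankdata, 0, vals)
    sd = ranks.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant metabolite(s); correlation treated as 0",
            stacklevel=3,
        )
    centered = ranks - ranks.mean(axis=0, keepdims=True)
    denom = np.where(const, 1.0, sd) * np.sqrt(n)
    norm = centered / denom
    rho = norm.T @ norm
    rho[const, :] = 0.0
    rho[:, const] = 0.0
    np.fill_diagonal(rho, 1.0)
    return rho


def prune_collinear(
    m: MetaboliteMatrix, rho_max: float = 0.5, absolute: bool = False
) -> tuple[MetaboliteMatrix, dict[str, str]]:
    """Keep one representative per collinear metabolite set.

    Metabolites are nodes; an edge joins any pair with Spearman rho >
    ``rho_max`` (on the signed rho by default; ``absolute=True`` uses |rho|).
    Within each connected component the metabolite with the highest variance
    of log values is kept (lexicographic id on ties). Returns the pruned
    matrix and a dropped -> kept mapping.
    """
    if m.intensities.shape[0] < 2:
        raise ValueError("need at least two samples to estimate correlations")
    vals = m.intensities.to_numpy(dtype=float)
    ids = list(m.intensities.columns)
    rho = _spearman_matrix(vals)
    crit = np.abs(rho) if absolute else rho
    adj = crit > rho_max
    np.fill_diagonal(adj, False)
    # connected components via scipy sparse
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    logvar = np.var(np.log(np.where(vals > 0, vals, np.nan)), axis=0)
    logvar = np.where(np.isfinite(logvar), logvar, -np.inf)
    kept, dropped = [], {}
    for c in range(n_comp):
        members = [ids[i] for i in np.where(labels == c)[0]]
        if len(members) == 1:
            kept.append(members[0])
            continue
        mv = sorted(
            members,
            key=lambda mid: (-logvar[ids.index(mid)], mid),
        )
        rep = mv[0]
        kept.append(rep)
        for other in members:
            if other != rep:
                dropped[other] = rep
    kept_in_order = [i for i in ids if i in set(kept)]
    pruned = m.copy_with(m.intensities.loc[:, kept_in_order])
    # cross-component representatives may still correlate; log, don't prune
    kept_idx = [ids.index(i) for i in kept_in_order]
    sub = crit[np.ix_(kept_idx, kept_idx)]
    np.fill_diagonal(sub, 0.0)
    if (sub > rho_max).any():
        log.info(
            "prune_collinear: %d retained cross-component pair(s) still exceed "
            "rho %.2f", int((sub > rho_max).sum() // 2), rho_max,
        )
    return pruned, dropped


def half_min_impute(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Replace zeros by half the smallest detected value of that metabolite."""
    vals = m.intensities.to_numpy(dtype=float).copy()
    if (vals <= 0).all(axis=0).any():
        bad = m.intensities.columns[(vals <= 0).all(axis=0)][0]
        raise ValueError(f"metabolite {bad!r} has no detected values")
    mins = np.nanmin(np.where(vals > 0, vals, np.nan), axis=0)
    zero = vals == 0
    vals[zero] = np.broadcast_to(mins / 2.0, vals.shape)[zero]
    return m.copy_with(pd.DataFrame(vals, index=m.intensities.index, columns=m.intensities.columns))


def log_standardize(m: MetaboliteMatrix | pd.DataFrame, standardize: bool = True) -> pd.DataFrame:
    """Natural log of intensities; optionally center and scale each metabolite
    to mean 0 / sd 1 (sd with n-1 denominator)."""
    df = m.intensities if isinstance(m, MetaboliteMatrix) else m
    vals = df.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("log transform requires strictly positive values (impute first)")
    logged = np.log(vals)
    if standardize:
        sd = logged.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = df.columns[sd == 0][0]
            raise ValueError(f"metabolite {bad!r} is constant; cannot standardize")
        logged = (logged - logged.mean(axis=0)) / sd
    return pd.DataFrame(logged, index=df.index, columns=df.columns)


def prepare_metabolome(
    m: MetaboliteMatrix,
    max_undetected: float = 0.25,
    rho_max: float = 0.5,
    batch_mode: str = "per-metabolite",
    absolute_rho: bool = False,
):
    """Full QC cascade: batch_adjust -> detection_filter -> prune_collinear ->
    half_min_impute. Returns ``(prepared matrix, dropped map)``; apply
    :func:`log_standardize` for model-ready features."""
    adj = batch_adjust(m, mode=batch_mode)
    det = detection_filter(adj, max_undetected)
    pruned, dropped = prune_collinear(det, rho_max, absolute=absolute_rho)
    imputed = half_min_impute(pruned)
    return imputed, dropped
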
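"""Compositional transforms, ordination, and permutation tests.

Microbiome count data are compositional: only relative information is
meaningful. The centered log-ratio (clr) transform maps each sample's
composition into real space where Euclidean geometry applies; the Euclidean
distance between clr vectors is the Aitchison distance. Group separation on a
distance matrix is tested with PERMANOVA (the ``adonis`` pseudo-F with a
permutation p-value), ordination uses classical PCoA, and the heatmap sample
grouping uses classic Ward.D agglomeration (Lance-Williams update on
unsquared distances, matching R's ``hclust(method="ward.D")``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DistanceMatrix:
    ids: list
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(self.d)).max(initial=0.0) > 1e-10:
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")


@dataclass
class PermanovaResult:
    pseudo_F: float
    r2: float
    p_value: float
    n_perm: int


def clr_transform(x, pseudocount: float = 0.5) -> np.ndarray:
    """Centered log-ratio transform, row-wise.

    Adds ``pseudocount`` to every entry, closes each row to proportions,
    takes logs and centers each row to mean zero. Output rows sum to ~0 and
    are invariant to rescaling a row by a positive constant.
    """
    if isinstance(x, pd.DataFrame):
        arr = x.to_numpy(dtype=float)
        out = clr_transform(arr, pseudocount)
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
        return clr_transform(arr, pseudocount)[0]
    if (arr < 0).any():
        raise ValueError("clr input must be nonnegative")
    zero_rows = np.where(arr.sum(axis=1) + pseudocount * arr.shape[1] <= 0)[0]
    if len(zero_rows):
        raise ValueError(f"all-zero row(s) with zero pseudocount: index {zero_rows[0]}")
    arr = arr + pseudocount
    if (arr <= 0).any():
        bad = int(np.where((arr <= 0).any(axis=1))[0][0])
        raise ValueError(f"nonpositive entries after pseudocount in row {bad}")
    logp = np.log(arr / arr.sum(axis=1, keepdims=True))
    return logp - logp.mean(axis=1, keepdims=True)


def aitchison_distance(clr_matrix, ids=None) -> DistanceMatrix:
    """Pairwise Euclidean distance between clr-transformed rows."""
    if isinstance(clr_matrix, pd.DataFrame):
        ids = list(clr_matrix.index)
        clr_matrix = clr_matrix.to_numpy(dtype=float)
    arr = np.asarray(clr_matrix, dtype=float)
    if ids is None:
        ids = list(range(arr.shape[0]))
    from scipy.spatial.distance import squareform, pdist

    d = squareform(pdist(arr, metric="euclidean"))
    return DistanceMatrix(ids, d)


def pcoa(d: DistanceMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical metric MDS (principal coordinates analysis).

    Double-centers the squared distance matrix, eigendecomposes, and returns
    coordinates on the top-``k`` positive-eigenvalue axes together with the
    fraction of positive-eigenvalue variance each axis explains.
    """
    n = len(d.ids)
    d2 = d.d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-10, 1e-10 * abs(vals[0]))
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        k = n_pos
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    explained = vals[:k] / vals[:n_pos].sum() if n_pos else np.zeros(0)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=pd.Index(d.ids), columns=cols), explained


def _permanova_f(d2: np.ndarray, groups: np.ndarray, uniq: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances (Anderson's direct formulation).

    SS_total = sum of squared distances / n; SS_within = sum over groups of
    within-group squared distances / group size.
    """
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.where(groups == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    a = len(uniq)
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    r2 = ss_among / ss_total
    return f, r2


def permanova(
    d: DistanceMatrix, groups, n_perm: int = 999, seed: int | None = None
) -> PermanovaResult:
    """One-way PERMANOVA (adonis) with a seeded label-permutation p-value.

    ``p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)`` — the observed statistic
    is counted in the null set.
    """
    groups = np.asarray(groups)
    if len(groups) != len(d.ids):
        raise ValueError("group labels must match distance matrix ids")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    d2 = d.d ** 2
    f_obs, r2 = _permanova_f(d2, groups, uniq)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        f_p, _ = _permanova_f(d2, perm, uniq)
        if f_p >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


def group_compare(
    values,
    groups,
    correction: str = "none",
    m: int = 1,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two groups, with optional
    Bonferroni correction for ``m`` tests.

    Uses the exact null distribution when both groups have <= 10 observations
    and no ties; otherwise the normal approximation with tie correction.
    Constant pooled data returns p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError("group_compare requires exactly two groups")
    a = values[groups == uniq[0]]
    b = values[groups == uniq[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("each group needs at least one observation")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    has_ties = len(np.unique(values)) < len(values)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if correction == "bonferroni":
        p = min(1.0, p * m)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return float(res.statistic), p


def _ward_d_linkage(d: np.ndarray) -> list[tuple[int, int, float]]:
    """Classic Ward.D agglomeration: Lance-Williams update applied to the
    dissimilarities as given (not squared). Ties break to the lowest pair of
    cluster indices. Returns merge list [(i, j, height)] using a scipy-style
    cluster numbering (new cluster n + step)."""
    n = d.shape[0]
    cur = d.astype(float).copy()
    np.fill_diagonal(cur, np.inf)
    sizes = np.ones(n)
    alive = np.ones(n, dtype=bool)
    labels = np.arange(n)
    merges = []
    for step in range(n - 1):
        masked = np.where(alive[:, None] & alive[None, :], cur, np.inf)
        # lowest-index tie-break: flat argmin scans row-major, first hit wins
        flat = int(np.argmin(masked))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        h = float(masked[i, j])
        ni, nj = sizes[i], sizes[j]
        merges.append((int(labels[i]), int(labels[j]), h))
        others = alive.copy()
        others[[i, j]] = False
        nk = sizes[others]
        new = ((ni + nk) * cur[i, others] + (nj + nk) * cur[j, others] - nk * h) / (
            ni + nj + nk
        )
        cur[i, others] = new
        cur[others, i] = new
        alive[j] = False
        sizes[i] = ni + nj
        labels[i] = n + step
    return merges


def ward_groups(
    x, n_groups: int = 3, scale: str | None = "row"
) -> np.ndarray:
    """Ward.D hierarchical clustering of rows, cut to ``n_groups`` labels.

    ``scale="row"`` standardizes each row to mean 0 / sd 1 before computing
    Euclidean distances (heatmap row-scaling convention); ``"column"`` scales
    columns; ``None`` uses the data as given.
    """
    arr = np.asarray(x, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("input must be finite")
    if n_groups > arr.shape[0]:
        raise ValueError("n_groups exceeds number of rows")
    if scale == "row":
        sd = arr.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        arr = (arr - arr.mean(axis=1, keepdims=True)) / sd
    elif scale == "column":
        sd = arr.std(axis=0, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        arr = (arr - arr.mean(axis=0, keepdims=True)) / sd
    elif scale is not None:
        raise ValueError(f"unknown scale {scale!r}")
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(arr, metric="euclidean"))
    merges = _ward_d_linkage(d)
    # cut: replay merges until n_groups clusters remain
    n = arr.shape[0]
    parent = list(range(2 * n - 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for step, (a, b, _) in enumerate(merges[: n - n_groups]):
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new
    roots = {}
    out = np.empty(n, dtype=int)
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        out[i] = roots[r]
    return out
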
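"""Metabolite-level outcome models for a binary clinical endpoint.

Three complementary views of "which serum metabolites track grade II-IV
aGVHD":

* :func:`logistic_lasso_stability` — glmnet-style 10-fold cross-validated
  logistic lasso on log metabolite levels with the GVHD prophylaxis regimen
  as an unpenalized covariate; coefficients at lambda_min are averaged across
  the fold fits, and the whole procedure is repeated under fresh random
  partitions to estimate per-feature selection probabilities.
* :func:`tune_splsda` / :func:`fit_splsda` — sparse partial least squares
  discriminant analysis with (n_components, keepX) tuned by repeated
  cross-validated balanced error rate; component-1 loadings are the
  loading-plot semantics.
* :func:`pca_scores` — plain PCA scores of the log-standardized matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .zerosum import _as_xy, _covar_array, cv_lambda, lambda_grid


def logistic_lasso_stability(
    X,
    y,
    covariate=None,
    n_folds: int = 10,
    n_repeats: int = 100,
    seed: int | None = None,
    n_lambda: int = 100,
    decades: float = 4.0,
    permute_y: bool = False,
) -> pd.DataFrame:
    """Stability-selected logistic lasso with an unpenalized covariate.

    ``permute_y`` draws a fresh outcome permutation per repeat (null
    calibration mode).

    Per repeat: stratified ``n_folds``-fold CV over a log-spaced lambda path
    picks lambda_min by mean held-out binomial deviance; the per-fold
    coefficient vectors at lambda_min are averaged, and a feature counts as
    selected when its averaged coefficient is nonzero. Selection
    probabilities, mean coefficients and signs are aggregated over repeats.
    The covariate is never penalized, so it stays in every model.
    """
    Xa, ya, names = _as_xy(X, y)
    C, cov_names = _covar_array(covariate, Xa.shape[0])
    grid = lambda_grid(Xa, ya, covariate, n_lambda=n_lambda, decades=decades)
    ss = np.random.SeedSequence(seed).spawn(n_repeats)
    p = Xa.shape[1]
    ncov = C.shape[1]
    sel = np.zeros((n_repeats, p + ncov))
    coefs = np.zeros((n_repeats, p + ncov))
    for r, child in enumerate(ss):
        rng = np.random.default_rng(child)
        yr = rng.permutation(ya) if permute_y else ya
        lam_min, _, fold_fits, _ = cv_lambda(
            Xa, yr, n_folds=n_folds, grid=grid,
            seed=int(rng.integers(2**31 - 1)), covariates=covariate,
            zero_sum=False, return_fold_fits=True,
        )
        li = int(np.argmin(np.abs(grid - lam_min)))
        b = np.mean([f[li].beta.to_numpy() for f in fold_fits], axis=0)
        cv = np.mean([f[li].covariate_coefs.to_numpy() for f in fold_fits], axis=0)
        full = np.concatenate([b, cv])
        sel[r] = np.abs(full) > 1e-12
        coefs[r] = full
    idx = pd.Index(list(names) + list(cov_names), name="feature_id")
    out = pd.DataFrame(
        {
            "selection_probability": sel.mean(axis=0),
            "mean_coefficient": coefs.mean(axis=0),
            "n_runs": n_repeats,
            "is_covariate": [False] * p + [True] * ncov,
        },
        index=idx,
    )
    out["sign"] = np.sign(out["mean_coefficient"]).map({1.0: "+", -1.0: "-", 0.0: "0"})
    return out.sort_values("selection_probability", ascending=False, kind="stable")


@dataclass
class SplsdaModel:
    n_components: int
    keepX: list[int]
    loadings: pd.DataFrame  # features x components, unit-norm columns
    scores: pd.DataFrame  # training samples x components
    x_mean: np.ndarray = field(repr=False, default=None)
    x_loadings_reg: np.ndarray = field(repr=False, default=None)  # deflation regressors
    centroids: dict = field(default_factory=dict)
    classes: list = field(default_factory=list)
    ber_by_config: pd.DataFrame | None = None


def fit_splsda(X, y, n_components: int = 2, keepX=None) -> SplsdaModel:
    """Sparse PLS-DA: per component the weight vector is the top-``keepX``
    entries (by magnitude) of the deflated covariance direction X'y,
    renormalized; X and y are deflated by the score regression."""
    if isinstance(X, pd.DataFrame):
        names, sample_ids = list(X.columns), list(X.index)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
        sample_ids = list(range(Xa.shape[0]))
    ya = np.asarray(y)
    classes = sorted(pd.unique(ya).tolist())
    if len(classes) != 2:
        raise ValueError("sPLS-DA here supports exactly two classes")
    n, p = Xa.shape
    if keepX is None:
        keepX = [min(10, p)] * n_components
    keepX = list(keepX)
    if len(keepX) < n_components:
        keepX = keepX + [keepX[-1]] * (n_components - len(keepX))
    for h, kx in enumerate(keepX):
        if kx > p:
            warnings.warn(f"keepX[{h}]={kx} exceeds {p} features; capping", stacklevel=2)
            keepX[h] = p
    x_mean = Xa.mean(axis=0)
    Xd = Xa - x_mean
    yd = (ya == classes[1]).astype(float)
    yd = yd - yd.mean()
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    Creg = np.zeros((p, n_components))
    for h in range(n_components):
        w = Xd.T @ yd
        if np.allclose(w, 0):
            w = np.ones(p)
        keep = np.argsort(-np.abs(w))[: keepX[h]]
        mask = np.zeros(p, dtype=bool)
        mask[keep] = True
        w = np.where(mask, w, 0.0)
        w = w / np.linalg.norm(w)
        t = Xd @ w
        tt = float(t @ t)
        c = Xd.T @ t / tt
        Xd = Xd - np.outer(t, c)
        yd = yd - t * float(t @ yd) / tt
        W[:, h], T[:, h], Creg[:, h] = w, t, c
    scores = pd.DataFrame(T, index=sample_ids, columns=[f"comp{h+1}" for h in range(n_components)])
    centroids = {
        cls: T[np.asarray(ya) == cls].mean(axis=0) for cls in classes
    }
    return SplsdaModel(
        n_components=n_components,
        keepX=keepX,
        loadings=pd.DataFrame(W, index=names, columns=scores.columns),
        scores=scores,
        x_mean=x_mean,
        x_loadings_reg=Creg,
        centroids=centroids,
        classes=classes,
    )


def splsda_predict(model: SplsdaModel, X) -> np.ndarray:
    """Class prediction by nearest class centroid in score space."""
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Xd = Xa - model.x_mean
    T = np.zeros((Xa.shape[0], model.n_components))
    for h in range(model.n_components):
        t = Xd @ model.loadings.iloc[:, h].to_numpy()
        T[:, h] = t
        Xd = Xd - np.outer(t, model.x_loadings_reg[:, h])
    dists = np.stack(
        [np.linalg.norm(T - model.centroids[c][None, :], axis=1) for c in model.classes],
        axis=1,
    )
    return np.asarray(model.classes, dtype=object)[np.argmin(dists, axis=1)]


def balanced_error_rate(y_true, y_pred) -> float:
    """Mean of per-class misclassification rates."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    rates = []
    for cls in np.unique(y_true):
        mask = y_true == cls
        rates.append(float((y_pred[mask] != cls).mean()))
    return float(np.mean(rates))


def tune_splsda(
    X,
    y,
    max_components: int = 2,
    keepX_grid=(5, 10, 20, 50),
    n_folds: int = 4,
    n_repeats: int = 100,
    seed: int | None = None,
) -> SplsdaModel:
    """Select (n_components, keepX) minimizing the mean balanced error rate
    over ``n_repeats`` runs of stratified ``n_folds``-fold CV, then fit the
    chosen configuration on the full data.

    Ties prefer fewer components, then smaller keepX. The tuning table (mean
    BER and its Monte-Carlo standard deviation per configuration) is attached
    to the returned model as ``ber_by_config``.
    """
    from sklearn.model_selection import StratifiedKFold

    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    ya = np.asarray(y)
    p = Xa.shape[1]
    keepX_grid = sorted({min(kx, p) for kx in keepX_grid})
    configs = [
        (nc, kx) for nc in range(1, max_components + 1) for kx in keepX_grid
    ]
    ss = np.random.SeedSequence(seed).spawn(n_repeats)
    bers = {cfg: [] for cfg in configs}
    for child in ss:
        rng = np.random.default_rng(child)
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        folds = list(skf.split(Xa, ya))
        for cfg in configs:
            nc, kx = cfg
            preds = np.empty(len(ya), dtype=object)
            for tr, te in folds:
                m = fit_splsda(Xa[tr], ya[tr], n_components=nc, keepX=[kx] * nc)
                preds[te] = splsda_predict(m, Xa[te])
            bers[cfg].append(balanced_error_rate(ya, preds))
    rows = [
        {
            "n_components": nc,
            "keepX": kx,
            "mean_ber": float(np.mean(bers[(nc, kx)])),
            "ber_mc_sd": float(np.std(bers[(nc, kx)], ddof=1)) if n_repeats > 1 else 0.0,
        }
        for nc, kx in configs
    ]
    table = pd.DataFrame(rows)
    best = table.sort_values(["mean_ber", "n_components", "keepX"]).iloc[0]
    model = fit_splsda(
        X, y, n_components=int(best["n_components"]),
        keepX=[int(best["keepX"])] * int(best["n_components"]),
    )
    model.ber_by_config = table
    return model


def pca_scores(X, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """SVD-based principal component scores and explained-variance fractions.

    Input should already be centered (e.g. log-standardized metabolite
    levels). Sign convention: the largest-magnitude loading of each component
    is positive. ``k`` beyond the matrix rank truncates with a warning.
    """
    if isinstance(X, pd.DataFrame):
        idx = X.index
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        idx = pd.RangeIndex(Xa.shape[0])
    Xc = Xa - Xa.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max(initial=0) * max(Xc.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if k > rank:
        warnings.warn(f"requested {k} components but rank is {rank}; truncating", stacklevel=2)
        k = rank
    # deterministic sign: largest-|loading| entry of each right vector positive
    for i in range(k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = u[:, :k] * s[:k]
    explained = (s**2 / (s**2).sum())[:k]
    cols = [f"PC{i+1}" for i in range(k)]
    return pd.DataFrame(scores, index=idx, columns=cols), explained
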
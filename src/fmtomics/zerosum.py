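"""Zero-sum constrained log-ratio lasso for binary outcomes, with
cross-validated penalty selection and repeated-run stability selection.

Model: logistic regression on per-sample log relative abundances with an L1
penalty and the linear constraint ``sum(beta) = 0`` over the penalized
features. Under the constraint the linear predictor depends only on
log-ratios between features, so fitted probabilities are invariant to
per-sample sequencing depth. The constraint is enforced by an augmented
Lagrangian outer loop; each subproblem is solved by iteratively reweighted
least squares with cyclic coordinate descent and soft thresholding
(glmnet-style). The same solver with the constraint switched off and
per-feature penalty factors is a plain logistic lasso and backs the
metabolite outcome models.

Stability selection repeats the whole cross-validation under fresh fold
partitions and reports, per feature, the fraction of runs in which it was
selected (nonzero at that run's lambda_min), the mean coefficient, and the
sign — the semantics of a selection-probability ranking plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=False)
def _cd_sweeps(X, w, z_res, beta, pf, in_con, lam, mu, rho, s, intercept, tol, max_sweeps):
    """Cyclic coordinate descent on the weighted least-squares subproblem.

    ``z_res`` is the working residual z - intercept - X @ beta (updated in
    place). ``s`` is the running sum of constrained coefficients. Penalized
    coordinates are soft-thresholded; pf[j] == 0 coordinates are unpenalized.
    """
    n, p = X.shape
    # per-coordinate curvature is fixed within one IRLS solve
    den0 = np.empty(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += w[i] * X[i, j] * X[i, j]
        den0[j] = acc / n
    wsum = 0.0
    for i in range(n):
        wsum += w[i]
    active = np.empty(p, np.bool_)
    for j in range(p):
        active[j] = beta[j] != 0.0
    # alternate full passes (which refresh the active set) with cheap passes
    # over the active coordinates only
    full_pass = True
    for sweep in range(max_sweeps):
        max_delta = 0.0
        num = 0.0
        for i in range(n):
            num += w[i] * z_res[i]
        d0 = num / wsum
        if d0 != 0.0:
            intercept += d0
            for i in range(n):
                z_res[i] -= d0
            if abs(d0) > max_delta:
                max_delta = abs(d0)
        for j in range(p):
            if not full_pass and not active[j]:
                continue
            bj = beta[j]
            dot = 0.0
            for i in range(n):
                dot += w[i] * X[i, j] * z_res[i]
            num = dot / n + den0[j] * bj
            den = den0[j]
            if in_con[j]:
                num -= mu + rho * (s - bj)
                den += rho
            if den <= 0.0:
                continue
            thr = lam * pf[j]
            if num > thr:
                new = (num - thr) / den
            elif num < -thr:
                new = (num + thr) / den
            else:
                new = 0.0
            d = new - bj
            if d != 0.0:
                for i in range(n):
                    z_res[i] -= X[i, j] * d
                if in_con[j]:
                    s += d
                beta[j] = new
                active[j] = new != 0.0
                if abs(d) > max_delta:
                    max_delta = abs(d)
        if full_pass:
            if max_delta < tol:
                break
            full_pass = False
        elif max_delta < tol:
            full_pass = True
    return intercept, s


def _sigmoid(eta):
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def binomial_deviance(y, eta):
    """Total binomial deviance 2*sum(log(1+e^eta) - y*eta)."""
    # log(1+e^eta) computed stably
    lse = np.logaddexp(0.0, eta)
    return float(2.0 * np.sum(lse - y * eta))


@dataclass
class ZeroSumFit:
    beta: pd.Series
    intercept: float
    covariate_coefs: pd.Series
    lam: float
    deviance: float
    constraint_residual: float
    converged: bool


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float).ravel()
    if set(np.unique(ya)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if Xa.shape[0] != ya.shape[0]:
        raise ValueError("X and y length mismatch")
    return Xa, ya, names


def _covar_array(covariates, n):
    if covariates is None:
        return np.empty((n, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    if isinstance(covariates, pd.Series):
        return covariates.to_numpy(dtype=float)[:, None], [covariates.name or "covariate"]
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"covar{j}" for j in range(arr.shape[1])]


def fit_zero_sum(
    X,
    y,
    lam: float,
    covariates=None,
    zero_sum: bool = True,
    penalty_factor=None,
    tol: float = 1e-8,
    constraint_tol: float = 1e-6,
    max_outer: int = 8,
    max_irls: int = 30,
    warm=None,
) -> ZeroSumFit:
    """Penalized logistic fit at one ``lam``.

    Minimizes ``(1/n) * binomial negative log-likelihood + lam * sum(pf |beta|)``
    subject to ``sum(beta) = 0`` over penalized features when ``zero_sum``.
    Covariate columns are appended unpenalized and unconstrained.
    """
    Xa, ya, names = _as_xy(X, y)
    C, cov_names = _covar_array(covariates, Xa.shape[0])
    p = Xa.shape[1]
    if p < 2 and zero_sum:
        raise ValueError("zero-sum constraint needs at least two penalized features")
    if penalty_factor is None:
        pf_pen = np.ones(p)
    else:
        pf_pen = np.asarray(penalty_factor, dtype=float)
    if np.any(pf_pen > 0):
        spans = Xa[:, pf_pen > 0].max(axis=0) - Xa[:, pf_pen > 0].min(axis=0)
        if Xa.shape[0] > 1 and np.any(spans == 0):
            raise ValueError("constant column among penalized features")
    full = np.ascontiguousarray(np.hstack([Xa, C]))
    pf = np.concatenate([pf_pen, np.zeros(C.shape[1])])
    in_con = np.concatenate(
        [(pf_pen > 0) if zero_sum else np.zeros(p, dtype=bool), np.zeros(C.shape[1], dtype=bool)]
    )
    n = full.shape[0]
    if warm is not None:
        beta = warm[0].copy()
        intercept = float(warm[1])
        mu = float(warm[2]) if len(warm) > 2 and zero_sum else 0.0
        rho = float(warm[3]) if len(warm) > 3 and zero_sum else (1.0 if zero_sum else 0.0)
    else:
        beta = np.zeros(full.shape[1])
        intercept = float(np.log((ya.mean() + 1e-12) / (1 - ya.mean() + 1e-12)))
        mu = 0.0
        rho = 1.0 if zero_sum else 0.0
    converged = True
    n_outer = max_outer if zero_sum else 1
    for outer in range(n_outer):
        prev_irls = None
        prev_obj = None
        for _ in range(max_irls):
            eta = full @ beta + intercept
            prob = _sigmoid(eta)
            w = np.clip(prob * (1 - prob), 1e-5, None)
            z = eta + (ya - prob) / w
            z_res = z - eta
            s = float(beta[in_con].sum())
            intercept, s = _cd_sweeps(
                full, w, z_res, beta, pf, in_con, lam, mu, rho, s, intercept,
                tol, 300,
            )
            cur = np.concatenate([[intercept], beta])
            if prev_irls is not None and np.max(np.abs(cur - prev_irls)) < 1e-7:
                break
            # near separation the coefficients creep while the penalized
            # objective is flat; stop on objective stagnation too
            obj = binomial_deviance(ya, full @ beta + intercept) / (2 * n) + lam * float(
                np.abs(beta * pf).sum()
            )
            if prev_obj is not None and abs(prev_obj - obj) < 1e-9 * max(1.0, abs(prev_obj)):
                break
            prev_irls, prev_obj = cur, obj
        else:
            converged = False
        s = float(beta[in_con].sum())
        if not zero_sum or abs(s) <= constraint_tol:
            break
        mu += rho * s
        rho = min(rho * 10.0, 1e6)
    resid = abs(float(beta[in_con].sum())) if zero_sum else 0.0
    eta = full @ beta + intercept
    fit = ZeroSumFit(
        beta=pd.Series(beta[:p], index=names),
        intercept=float(intercept),
        covariate_coefs=pd.Series(beta[p:], index=cov_names),
        lam=float(lam),
        deviance=binomial_deviance(ya, eta),
        constraint_residual=resid,
        converged=converged,
    )
    fit._warm = (beta.copy(), float(intercept), mu, rho)  # for path continuation
    return fit


def logratio_features(t, pseudocount: float = 0.5) -> pd.DataFrame:
    """Log relative abundances: ``log((count + pc) / (row total + G * pc))``.

    Under a zero-sum coefficient vector the linear predictor built from these
    features equals a sum of pairwise log-ratios, hence is invariant to
    per-sample sequencing depth.
    """
    from .prep import CountTable

    df = t.counts if isinstance(t, CountTable) else t
    if df.shape[1] < 2:
        raise ValueError("log-ratio features need at least two taxa")
    arr = df.to_numpy(dtype=float) + pseudocount
    tot = arr.sum(axis=1, keepdims=True)
    return pd.DataFrame(np.log(arr / tot), index=df.index, columns=df.columns)


def lambda_grid(
    X, y, covariates=None, n_lambda: int = 100, decades: float = 4.0,
    penalty_factor=None,
) -> np.ndarray:
    """Log-spaced grid from lambda_max (null model boundary) down ``decades``
    decades. lambda_max is the largest penalized-gradient magnitude at the
    covariate-only null fit."""
    Xa, ya, _ = _as_xy(X, y)
    null = fit_zero_sum(
        X, y, lam=1e12, covariates=covariates, zero_sum=False,
        penalty_factor=penalty_factor,
    )
    C, _ = _covar_array(covariates, Xa.shape[0])
    eta = C @ null.covariate_coefs.to_numpy() + null.intercept if C.shape[1] else np.full(len(ya), null.intercept)
    grad = np.abs(Xa.T @ (ya - _sigmoid(eta))) / len(ya)
    pf = np.ones(Xa.shape[1]) if penalty_factor is None else np.asarray(penalty_factor, float)
    with np.errstate(divide="ignore"):
        lam_max = float(np.max(np.where(pf > 0, grad / np.where(pf > 0, pf, 1.0), 0.0)))
    lam_max = max(lam_max, 1e-6) * 1.001
    return np.geomspace(lam_max, lam_max * 10 ** (-decades), n_lambda)


def _check_folds(y, n_folds):
    y = np.asarray(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if min(n0, n1) < n_folds:
        raise ValueError(
            f"cannot stratify {n_folds} folds with class counts ({n0}, {n1})"
        )


def _stratified_folds(y, n_folds, rng):
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(
        n_splits=n_folds, shuffle=True,
        random_state=int(rng.integers(2**31 - 1)),
    )
    return list(skf.split(np.zeros(len(y)), y))


def _path_fits(X, y, grid, covariates, zero_sum, penalty_factor):
    """Warm-started fits along a decreasing lambda grid.

    The path stops early (remaining fits reuse the last solution) once the
    model explains essentially all deviance or saturates in nonzero
    coefficients, which avoids the near-separation regime at tiny lambda."""
    _, ya, _ = _as_xy(X, y)
    n = len(ya)
    pbar = ya.mean()
    dev_null = binomial_deviance(ya, np.full(n, np.log(pbar / (1 - pbar))))
    fits = []
    warm = None
    for lam in grid:
        f = fit_zero_sum(
            X, y, lam, covariates=covariates, zero_sum=zero_sum,
            penalty_factor=penalty_factor, warm=warm,
        )
        warm = f._warm
        fits.append(f)
        nnz = int((f.beta.to_numpy() != 0).sum())
        if dev_null > 0 and (1 - f.deviance / dev_null > 0.999 or nnz >= min(n, f.beta.size)):
            break
    while len(fits) < len(grid):
        fits.append(fits[-1])
    return fits


def cv_lambda(
    X,
    y,
    n_folds: int = 4,
    grid=None,
    seed: int | None = None,
    covariates=None,
    zero_sum: bool = True,
    n_lambda: int = 100,
    decades: float = 4.0,
    penalty_factor=None,
    folds=None,
    return_fold_fits: bool = False,
):
    """Stratified k-fold cross-validation over a lambda path.

    Returns ``(lambda_min, cv table)`` where the table holds mean held-out
    binomial deviance per lambda; with ``return_fold_fits`` also returns the
    per-fold path fits (used for fold-averaged coefficients).
    """
    Xa, ya, _ = _as_xy(X, y)
    _check_folds(ya, n_folds)
    if grid is None:
        grid = lambda_grid(
            X, y, covariates, n_lambda=n_lambda, decades=decades,
            penalty_factor=penalty_factor,
        )
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    if folds is None:
        folds = _stratified_folds(ya, n_folds, rng)
    C, _ = _covar_array(covariates, Xa.shape[0])
    dev = np.zeros((len(folds), len(grid)))
    fold_fits = []
    for fi, (tr, te) in enumerate(folds):
        cov_tr = C[tr] if C.shape[1] else None
        fits = _path_fits(Xa[tr], ya[tr], grid, cov_tr, zero_sum, penalty_factor)
        fold_fits.append(fits)
        for li, f in enumerate(fits):
            eta = Xa[te] @ f.beta.to_numpy() + f.intercept
            if C.shape[1]:
                eta = eta + C[te] @ f.covariate_coefs.to_numpy()
            dev[fi, li] = binomial_deviance(ya[te], eta) / len(te)
    mean_dev = dev.mean(axis=0)
    li_min = int(np.argmin(mean_dev))
    table = pd.DataFrame({"lam": grid, "mean_deviance": mean_dev})
    if return_fold_fits:
        return float(grid[li_min]), table, fold_fits, folds
    return float(grid[li_min]), table


def stability_select(
    X,
    y,
    n_runs: int = 100,
    n_folds: int = 4,
    seed: int | None = None,
    covariates=None,
    zero_sum: bool = True,
    n_lambda: int = 100,
    decades: float = 4.0,
    penalty_factor=None,
    permute_y: bool = False,
) -> pd.DataFrame:
    """Repeat fold-randomized CV ``n_runs`` times; per run refit the full data
    at that run's lambda_min and record which features are nonzero.

    ``permute_y`` draws a fresh outcome permutation per run — the null
    calibration mode: under it no feature should accumulate selections, since
    each run sees a different spurious correlate.

    Returns a table indexed by feature with columns ``selection_probability``,
    ``mean_coefficient``, ``sign`` and ``n_runs``, ranked by probability
    (desc), then |mean coefficient| (desc), then feature id.
    """
    Xa, ya, names = _as_xy(X, y)
    grid = lambda_grid(
        X, y, covariates, n_lambda=n_lambda, decades=decades,
        penalty_factor=penalty_factor,
    )
    ss = np.random.SeedSequence(seed).spawn(n_runs)
    # full-data refits depend only on lambda_min: cache the full path once
    full_path = _path_fits(Xa, ya, grid, covariates, zero_sum, penalty_factor)
    sel = np.zeros((n_runs, Xa.shape[1]))
    coefs = np.zeros((n_runs, Xa.shape[1]))
    for r, child in enumerate(ss):
        rng = np.random.default_rng(child)
        yr = rng.permutation(ya) if permute_y else ya
        lam_min, _ = cv_lambda(
            Xa, yr, n_folds=n_folds, grid=grid, seed=int(rng.integers(2**31 - 1)),
            covariates=covariates, zero_sum=zero_sum, penalty_factor=penalty_factor,
        )
        li = int(np.argmin(np.abs(grid - lam_min)))
        if permute_y:
            run_path = _path_fits(Xa, yr, grid[: li + 1], covariates, zero_sum, penalty_factor)
            b = run_path[li].beta.to_numpy()
        else:
            b = full_path[li].beta.to_numpy()
        sel[r] = b != 0
        coefs[r] = b
    out = pd.DataFrame(
        {
            "selection_probability": sel.mean(axis=0),
            "mean_coefficient": coefs.mean(axis=0),
            "n_runs": n_runs,
        },
        index=pd.Index(names, name="feature_id"),
    )
    out["sign"] = np.sign(out["mean_coefficient"]).map({1.0: "+", -1.0: "-", 0.0: "0"})
    out = (
        out.assign(_abs=out["mean_coefficient"].abs())
        .reset_index()
        .sort_values(
            by=["selection_probability", "_abs", "feature_id"],
            ascending=[False, False, True],
        )
        .set_index("feature_id")
        .drop(columns="_abs")
    )
    return out
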
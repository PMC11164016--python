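"""Latent Dirichlet allocation over genus count tables.

Samples play the role of documents, genera of words, and latent microbial
subcommunities ("clusters" / enterosignatures) of topics: each sample is a
mixture of topics and each topic is a distribution over genera. Inference is
batch variational EM (VEM): per-sample mean-field updates of topic
responsibilities and Dirichlet pseudo-counts in the E-step, topic-genus
probabilities in the M-step, and Newton updates of the symmetric document
Dirichlet concentration ``alpha``. Topic-genus rows carry a fixed smoothing
``eta`` (MAP under a symmetric Dirichlet prior); the tracked objective
includes the smoothing term so the trace is non-decreasing.

The number of topics is selected by minimizing the Cao density criterion
(mean pairwise cosine similarity between topic-genus rows) over a k range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, psi

from .prep import CountTable


@dataclass
class TopicModelResult:
    k: int
    topic_term: pd.DataFrame  # k x G, rows sum to 1
    sample_topics: pd.DataFrame  # N x k, rows sum to 1
    elbo_trace: list[float]
    alpha: float
    seed: int | None
    converged: bool
    gamma: np.ndarray = field(repr=False, default=None)  # N x k variational Dirichlet


def _elbo(W, gamma, beta, alpha, eta, ew_logphi_terms):
    """Variational bound (plus the eta log-prior on beta, so the VEM trace is
    monotone); ``ew_logphi_terms`` carries the E_q[log p(w,z)] - E_q[log q(z)]
    part accumulated during the E-step."""
    n, k = gamma.shape
    dig = psi(gamma) - psi(gamma.sum(axis=1, keepdims=True))
    l_theta = (
        n * (gammaln(k * alpha) - k * gammaln(alpha))
        + (alpha - 1) * dig.sum()
    )
    l_q_theta = (
        gammaln(gamma.sum(axis=1)).sum()
        - gammaln(gamma).sum()
        + ((gamma - 1) * dig).sum()
    )
    l_beta_prior = eta * np.log(beta).sum()
    return float(l_theta + ew_logphi_terms - l_q_theta + l_beta_prior)


def _e_step(W, beta, alpha, gamma, inner_tol=1e-4, max_inner=100):
    """Mean-field updates for all samples at once.

    The responsibilities ``phi[n, g, k] = t[n, k] * beta[k, g] / denom[n, g]``
    (with ``t = exp(E_q[log theta])`` and ``denom = t @ beta``) are never
    materialized: both the gamma update and the sufficient statistics reduce
    to matrix products, and the z/w part of the bound collapses to
    ``sum(W * log(denom))``.

    Returns updated gamma, the expected word-topic counts ``ss`` (k x G,
    the M-step sufficient statistics), and the z/w bound term.
    """
    for _ in range(max_inner):
        t = np.exp(psi(gamma) - psi(gamma.sum(axis=1, keepdims=True)))  # N x k
        denom = t @ beta + 1e-300  # N x G
        new_gamma = alpha + t * ((W / denom) @ beta.T)
        delta = np.abs(new_gamma - gamma).mean()
        gamma = new_gamma
        if delta < inner_tol * max(1.0, gamma.mean()):
            break
    t = np.exp(psi(gamma) - psi(gamma.sum(axis=1, keepdims=True)))
    denom = t @ beta + 1e-300
    ratio = W / denom
    ss = beta * (t.T @ ratio)
    zw = float((W * np.log(denom)).sum())
    return gamma, ss, zw


def _alpha_objective(gamma, alpha):
    n, k = gamma.shape
    dig = (psi(gamma) - psi(gamma.sum(axis=1, keepdims=True))).sum()
    return n * (gammaln(k * alpha) - k * gammaln(alpha)) + (alpha - 1) * dig


def _update_alpha(gamma, alpha, max_newton=20):
    """Newton iterations in log-alpha for the symmetric Dirichlet concentration,
    with a backtracking safeguard so the objective never decreases."""
    n, k = gamma.shape
    suff = (psi(gamma) - psi(gamma.sum(axis=1, keepdims=True))).sum()
    obj = _alpha_objective(gamma, alpha)
    for _ in range(max_newton):
        g = n * k * (psi(k * alpha) - psi(alpha)) + suff
        from scipy.special import polygamma

        h = n * k * (k * polygamma(1, k * alpha) - polygamma(1, alpha))
        # Newton in log space: d/d(log a) = g*a ; d2 = h*a^2 + g*a
        step = (g * alpha) / (h * alpha * alpha + g * alpha)
        if not np.isfinite(step):
            break
        new = alpha * np.exp(-step)
        new = float(np.clip(new, 1e-4, 50.0))
        new_obj = _alpha_objective(gamma, new)
        tries = 0
        while new_obj < obj and tries < 10:
            new = float(np.sqrt(new * alpha))  # halve the log-step
            new_obj = _alpha_objective(gamma, new)
            tries += 1
        if new_obj < obj or abs(np.log(new / alpha)) < 1e-6:
            break
        alpha, obj = new, new_obj
    return alpha


def _fit_once(W, k, rng, eta, tol, max_iter, estimate_alpha):
    n, G = W.shape
    freq = W.sum(axis=0) + 1.0
    freq = freq / freq.sum()
    # perturbed-frequency init keeps topics distinct but data-anchored
    beta = freq[None, :] * np.exp(0.5 * rng.standard_normal((k, G)))
    beta /= beta.sum(axis=1, keepdims=True)
    alpha = 1.0 / k if k > 1 else 1.0
    gamma = np.full((n, k), alpha) + W.sum(axis=1, keepdims=True) / k
    trace = []
    converged = False
    # alpha updates start only after the topics have stabilized under the
    # fixed prior: joint updates from the start collapse alpha early and drag
    # the fit into a poorer local bound
    alpha_on = False
    for it in range(max_iter):
        gamma, ss, zw = _e_step(W, beta, alpha, gamma)
        # record the bound at (gamma, beta, alpha) as optimized so far; the
        # following M/alpha steps only increase it, so the trace is monotone
        trace.append(_elbo(W, gamma, beta, alpha, eta, zw))
        beta = ss + eta
        beta /= beta.sum(axis=1, keepdims=True)
        if alpha_on and k > 1:
            alpha = _update_alpha(gamma, alpha)
        if it > 0 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-2]):
            if estimate_alpha and not alpha_on and k > 1:
                alpha_on = True
                continue
            converged = True
            break
    return beta, gamma, alpha, trace, converged


def fit_lda(
    counts: CountTable | pd.DataFrame,
    k: int,
    seed: int | None = 0,
    tol: float = 1e-6,
    max_iter: int = 80,
    eta: float = 0.1,
    n_restarts: int = 5,
    estimate_alpha: bool = True,
) -> TopicModelResult:
    """Fit a k-topic LDA model to a genus count table by variational EM.

    Runs ``n_restarts`` seeded restarts and keeps the best-bound fit. ``k=1``
    is allowed for degenerate-case testing (topic equals the pooled genus
    frequencies). Empty samples are dropped with a warning; non-convergence
    at ``max_iter`` flags the result rather than raising.
    """
    df = counts.counts if isinstance(counts, CountTable) else counts
    W = df.to_numpy(dtype=float)
    if (W < 0).any():
        raise ValueError("counts must be nonnegative")
    nonempty = W.sum(axis=1) > 0
    if not nonempty.all():
        warnings.warn(f"dropping {int((~nonempty).sum())} empty sample(s)", stacklevel=2)
        df = df.loc[nonempty]
        W = W[nonempty]
    if k < 1:
        raise ValueError("k must be >= 1")
    ss = np.random.SeedSequence(seed).spawn(max(1, n_restarts))
    best = None
    for child in ss[: max(1, n_restarts)]:
        rng = np.random.default_rng(child)
        beta, gamma, alpha, trace, conv = _fit_once(
            W, k, rng, eta, tol, max_iter, estimate_alpha
        )
        if best is None or trace[-1] > best[3][-1]:
            best = (beta, gamma, alpha, trace, conv)
    beta, gamma, alpha, trace, conv = best
    theta = gamma / gamma.sum(axis=1, keepdims=True)
    topics = [f"topic{i + 1}" for i in range(k)]
    return TopicModelResult(
        k=k,
        topic_term=pd.DataFrame(beta, index=topics, columns=df.columns),
        sample_topics=pd.DataFrame(theta, index=df.index, columns=topics),
        elbo_trace=trace,
        alpha=float(alpha),
        seed=seed,
        converged=conv,
        gamma=gamma,
    )


def cao_density(topic_term: np.ndarray | pd.DataFrame) -> float:
    """Cao 2009 topic-density criterion: mean pairwise cosine similarity
    between topic-genus rows. Lower is better (more distinct topics)."""
    b = np.asarray(topic_term, dtype=float)
    k = b.shape[0]
    if k < 2:
        return 1.0
    norm = b / np.linalg.norm(b, axis=1, keepdims=True)
    cos = norm @ norm.T
    return float(cos[np.triu_indices(k, 1)].mean())


def select_k(
    counts: CountTable | pd.DataFrame,
    k_min: int = 2,
    k_max: int = 10,
    seed: int | None = 0,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame, dict[int, TopicModelResult]]:
    """Choose the topic count minimizing the Cao density criterion over
    ``k_min..k_max`` (ties go to the smaller k).

    Returns ``(k_star, score table, fitted models by k)``.
    """
    if not (2 <= k_min <= k_max):
        raise ValueError("need k_max >= k_min >= 2")
    rows = []
    fits = {}
    for i, k in enumerate(range(k_min, k_max + 1)):
        m = fit_lda(counts, k, seed=None if seed is None else seed + 1000 * i, **fit_kwargs)
        score = cao_density(m.topic_term)
        fits[k] = m
        rows.append({"k": k, "cao_density": score, "elbo": m.elbo_trace[-1]})
    table = pd.DataFrame(rows).set_index("k")
    k_star = int(table["cao_density"].idxmin())  # idxmin takes first = smallest k on ties
    return k_star, table, fits


def top_taxa(m: TopicModelResult, n: int = 5) -> dict[str, list[str]]:
    """Per-topic list of the ``n`` highest-probability genera, descending;
    exact probability ties break lexicographically by genus name."""
    if n > m.topic_term.shape[1]:
        raise ValueError("n exceeds number of genera")
    out = {}
    for topic, row in m.topic_term.iterrows():
        ordered = sorted(row.items(), key=lambda kv: (-kv[1], kv[0]))
        out[topic] = [g for g, _ in ordered[:n]]
    return out


def cluster_abundances(m: TopicModelResult) -> pd.DataFrame:
    """Sample x topic mixture weights as a composition (rows sum to 1),
    ready for clr transformation and distance-based testing."""
    return m.sample_topics.copy()
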
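"""Latent Dirichlet allocation fitted by batch variational Bayes.

The model: each document d mixes K topics through theta_d ~
Dirichlet(alpha); each topic k is a word distribution beta_k ~
Dirichlet(eta); every token draws a topic z ~ theta_d then a word
w ~ beta_z. Inference is mean-field coordinate ascent on the evidence
lower bound (ELBO) with the usual digamma updates: per-document
variational Dirichlet parameters gamma and a global topic-word
pseudo-count matrix lambda. Batch updates make every fit exactly
reproducible for a fixed seed, and the ELBO is non-decreasing across
iterations, which the tests assert.

A fitted model exposes the normalized posterior-mean simplexes
``phi`` (K x V topic-word) and ``theta`` (D x K document-topic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln, psi

from .corpus import DocTermMatrix

__all__ = [
    "TopicModel",
    "TopicCluster",
    "fit_lda",
    "top_words",
    "run_replicates",
    "clusters_from_models",
    "infer_theta",
    "perplexity",
]


@dataclass
class TopicModel:
    """Fitted LDA parameters plus the priors and seed that produced them."""

    K: int
    phi: np.ndarray  # K x V, rows sum to 1
    theta: np.ndarray  # D x K, rows sum to 1
    alpha: float
    eta: float
    seed: int
    n_iterations: int
    converged: bool
    elbo_trace: tuple[float, ...]
    lambda_: np.ndarray = field(repr=False, default=None)  # K x V variational
    gamma: np.ndarray = field(repr=False, default=None)  # D x K variational
    vocabulary: tuple[str, ...] = ()

    @property
    def elbo(self) -> float:
        return self.elbo_trace[-1]


@dataclass(frozen=True)
class TopicCluster:
    """One inferred topic rendered as its ranked top words."""

    run_id: int
    category: str
    topic: int
    words: tuple[str, ...]
    weights: tuple[float, ...]


def _dirichlet_expectation(x: np.ndarray) -> np.ndarray:
    """E[log p] for rows of Dirichlet parameters."""
    if x.ndim == 1:
        return psi(x) - psi(x.sum())
    return psi(x) - psi(x.sum(axis=1))[:, None]


def _e_step(
    X: sp.csr_matrix,
    expElogbeta: np.ndarray,
    alpha: float,
    gamma0: np.ndarray,
    inner_iter: int,
    inner_tol: float,
) -> tuple[np.ndarray, sp.csr_matrix]:
    """Update gamma for all documents; return (gamma, count/Z ratio matrix)."""
    gamma = gamma0
    Elogtheta = _dirichlet_expectation(gamma)
    expElogtheta = np.exp(Elogtheta)
    K = expElogbeta.shape[0]
    R = None
    for _ in range(inner_iter):
        Z = expElogtheta @ expElogbeta  # D x V, evaluated densely
        np.maximum(Z, 1e-100, out=Z)
        R = X.multiply(1.0 / Z).tocsr()  # n_dw / Z_dw, sparse
        new_gamma = alpha + expElogtheta * (R @ expElogbeta.T)
        delta = np.abs(new_gamma - gamma).mean() / K
        gamma = new_gamma
        expElogtheta = np.exp(_dirichlet_expectation(gamma))
        if delta < inner_tol:
            break
    Z = expElogtheta @ expElogbeta
    np.maximum(Z, 1e-100, out=Z)
    R = X.multiply(1.0 / Z).tocsr()
    return gamma, R


def _elbo(
    X: sp.csr_matrix,
    gamma: np.ndarray,
    lambda_: np.ndarray,
    alpha: float,
    eta: float,
) -> float:
    """Variational lower bound on log evidence (Hoffman-style bound)."""
    D, K = gamma.shape
    V = lambda_.shape[1]
    Elogtheta = _dirichlet_expectation(gamma)
    Elogbeta = _dirichlet_expectation(lambda_)
    # token term: sum_dw n_dw log sum_k exp(Elogtheta_dk + Elogbeta_kw)
    Z = np.exp(Elogtheta) @ np.exp(Elogbeta)
    np.maximum(Z, 1e-300, out=Z)
    rows, cols = X.nonzero()
    score = float(np.sum(X.data * np.log(Z[rows, cols])))
    # theta entropy / prior
    score += float(np.sum((alpha - gamma) * Elogtheta))
    score += float(np.sum(gammaln(gamma)) - np.sum(gammaln(gamma.sum(axis=1))))
    score += D * float(gammaln(K * alpha) - K * gammaln(alpha))
    # beta entropy / prior
    score += float(np.sum((eta - lambda_) * Elogbeta))
    score += float(np.sum(gammaln(lambda_)) - np.sum(gammaln(lambda_.sum(axis=1))))
    score += K * float(gammaln(V * eta) - V * gammaln(eta))
    return score


def fit_lda(
    dtm: DocTermMatrix,
    K: int,
    alpha: float | None = None,
    eta: float | None = None,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    inner_iter: int = 60,
    inner_tol: float = 1e-3,
) -> TopicModel:
    """Fit LDA with K topics by batch variational Bayes.

    Priors default to the symmetric alpha = eta = 1/K. The fit stops
    when the relative ELBO change drops below ``tol`` or after
    ``max_iter`` sweeps. Identical inputs and seed give identical
    models.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if dtm.n_docs == 0 or dtm.total_tokens() == 0:
        raise ValueError("cannot fit LDA on an empty corpus")
    if K > dtm.n_docs:
        warnings.warn(f"K={K} exceeds the number of documents ({dtm.n_docs})", stacklevel=2)
    if alpha is None:
        alpha = 1.0 / K
    if eta is None:
        eta = 1.0 / K

    X = dtm.counts.astype(float).tocsr()
    D, V = X.shape
    rng = np.random.default_rng(seed)
    lambda_ = rng.gamma(100.0, 1.0 / 100.0, (K, V))
    gamma = np.full((D, K), alpha + dtm.total_tokens() / (D * K))

    trace: list[float] = []
    converged = False
    n_done = 0
    for it in range(max_iter):
        expElogbeta = np.exp(_dirichlet_expectation(lambda_))
        gamma, R = _e_step(X, expElogbeta, alpha, gamma, inner_iter, inner_tol)
        expElogtheta = np.exp(_dirichlet_expectation(gamma))
        sstats = expElogbeta * (expElogtheta.T @ R)
        lambda_ = eta + sstats
        bound = _elbo(X, gamma, lambda_, alpha, eta)
        trace.append(bound)
        n_done = it + 1
        if it > 0:
            prev = trace[-2]
            if abs(bound - prev) / (abs(prev) + 1e-12) < tol:
                converged = True
                break

    phi = lambda_ / lambda_.sum(axis=1)[:, None]
    theta = gamma / gamma.sum(axis=1)[:, None]
    return TopicModel(
        K=K,
        phi=phi,
        theta=theta,
        alpha=alpha,
        eta=eta,
        seed=seed,
        n_iterations=n_done,
        converged=converged,
        elbo_trace=tuple(trace),
        lambda_=lambda_,
        gamma=gamma,
        vocabulary=dtm.vocabulary.words,
    )


def top_words(model: TopicModel, topic: int, n: int = 10) -> list[str]:
    """The n highest-weight words of a topic, descending; ties break
    lexicographically."""
    if not 0 <= topic < model.K:
        raise ValueError(f"topic index {topic} out of range for K={model.K}")
    V = model.phi.shape[1]
    if not 1 <= n <= V:
        raise ValueError(f"n must lie in [1, {V}]")
    vocab = model.vocabulary
    order = sorted(range(V), key=lambda j: (-model.phi[topic, j], vocab[j]))
    return [vocab[j] for j in order[:n]]


def run_replicates(
    dtm: DocTermMatrix,
    K: int,
    seeds: Sequence[int],
    **fit_kwargs,
) -> list[TopicModel]:
    """One independently initialized fit per seed (replicate runs)."""
    if len(set(seeds)) != len(seeds):
        raise ValueError("replicate seeds must be distinct")
    return [fit_lda(dtm, K, seed=s, **fit_kwargs) for s in seeds]


def clusters_from_models(
    models: Sequence[TopicModel],
    category: str = "all",
    n_words: int = 10,
) -> list[TopicCluster]:
    """Render every topic of every replicate as a ranked-top-word cluster."""
    clusters = []
    for run_id, model in enumerate(models):
        for t in range(model.K):
            words = top_words(model, t, n_words)
            idx = {w: i for i, w in enumerate(model.vocabulary)}
            weights = tuple(float(model.phi[t, idx[w]]) for w in words)
            clusters.append(
                TopicCluster(run_id=run_id, category=category, topic=t,
                             words=tuple(words), weights=weights)
            )
    return clusters


def infer_theta(
    model: TopicModel,
    dtm: DocTermMatrix,
    inner_iter: int = 100,
    inner_tol: float = 1e-3,
) -> np.ndarray:
    """Fold new documents into a fitted model (gamma for held-out docs)."""
    X = dtm.counts.astype(float).tocsr()
    D = X.shape[0]
    expElogbeta = np.exp(_dirichlet_expectation(model.lambda_))
    gamma0 = np.full((D, model.K), model.alpha + X.sum() / (D * model.K))
    gamma, _ = _e_step(X, expElogbeta, model.alpha, gamma0, inner_iter, inner_tol)
    return gamma


def perplexity(model: TopicModel, dtm: DocTermMatrix) -> float:
    """exp(-bound / token count) on the given documents.

    Matches the convention of variational LDA implementations that
    report perplexity from the full per-corpus bound.
    """
    gamma = infer_theta(model, dtm)
    bound = _elbo(dtm.counts.astype(float).tocsr(), gamma, model.lambda_,
                  model.alpha, model.eta)
    n_tokens = dtm.total_tokens()
    if n_tokens == 0:
        raise ValueError("no tokens in evaluation corpus")
    return float(np.exp(-bound / n_tokens))
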
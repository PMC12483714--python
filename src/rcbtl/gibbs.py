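"""Latent-exponential augmentation and the closed-form worth update.

Each non-trivial selection stage of each judge's ranking contributes one
denominator  sum_{j in remaining} lambda_j  to the BTL likelihood. Writing
1/d = integral_0^inf exp(-y d) dy introduces one latent

    y_{i,s} ~ Exponential(rate = sum_{j in remaining_{i,s}} lambda_j)

per stage; conditional on the latents the awkward denominators cancel and
the posterior of the cluster worths factorizes into independent Gammas:

    lambda*_k | g, data, Y  ~  Gamma(a + W_k,  b + R_k)

where W_k counts the stages whose selected object lies in cluster k and
R_k = sum_{i,s} y_{i,s} * #(cluster-k objects in remaining_{i,s}). Latents
are regenerated fresh on every call and never persisted across partition
moves, because the birth/death acceptance ratio lives on the non-augmented
posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import Hyperparams, Partition, RankingDataset, WorthState
from .likelihood import LogLikTerms

__all__ = [
    "LatentAugmentation",
    "sample_latents",
    "full_conditional_params",
    "worth_gibbs_update",
]


@dataclass(frozen=True)
class LatentAugmentation:
    """One positive latent per non-trivial (judge, stage), aligned with
    the stage rows of :class:`~rcbtl.likelihood.LogLikTerms`."""

    terms: LogLikTerms
    y: np.ndarray  # (T,) > 0

    def __post_init__(self) -> None:
        if self.y.shape != (self.terms.n_stages,):
            raise ValueError("one latent required per stage")
        if np.any(self.y <= 0):
            raise ValueError("latents must be strictly positive")


def _terms_of(data) -> LogLikTerms:
    return data if isinstance(data, LogLikTerms) else LogLikTerms.from_dataset(data)


def sample_latents(data, worths, rng: np.random.Generator) -> LatentAugmentation:
    """Draw y_{i,s} ~ Exp(rate = stage denominator) independently."""
    terms = _terms_of(data)
    w = np.asarray(worths, dtype=float)
    if np.any(w <= 0):
        raise ValueError("worths must be strictly positive")
    rates = terms.remaining @ w
    y = rng.exponential(scale=1.0 / rates) if terms.n_stages else np.empty(0)
    return LatentAugmentation(terms, y)


def full_conditional_params(
    g: Partition,
    data,
    latents: LatentAugmentation,
    hyper: Hyperparams,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster (shape, rate) of the Gamma full conditional.

    shape_k = a + number of stages won by cluster-k objects;
    rate_k  = b + sum over stages of y * (cluster-k objects still remaining).
    """
    terms = _terms_of(data)
    K = g.n_clusters
    assignment = np.asarray(g.assignment)
    shapes = hyper.a + np.bincount(
        assignment[terms.winner], minlength=K
    ).astype(float)
    per_object = latents.y @ terms.remaining  # (J,) total exposure of each object
    rates = hyper.b + np.bincount(assignment, weights=per_object, minlength=K)
    return shapes, rates


def _gibbs_sweep_terms(
    state: WorthState,
    terms: LogLikTerms | None,
    hyper: Hyperparams,
    rng: np.random.Generator,
) -> WorthState:
    g = state.partition
    K = g.n_clusters
    if terms is None or terms.n_stages == 0:
        shapes = np.full(K, hyper.a)
        rates = np.full(K, hyper.b)
    else:
        w = np.asarray(state.expanded_worths)
        latents = sample_latents(terms, w, rng)
        shapes, rates = full_conditional_params(g, terms, latents, hyper)
    while True:
        cw = rng.gamma(shapes, 1.0 / rates)
        if len(np.unique(cw)) == K:  # worth ties have probability 0
            return WorthState(g, cw)


def worth_gibbs_update_terms(
    state: WorthState,
    terms: LogLikTerms | None,
    hyper: Hyperparams,
    rng: np.random.Generator,
    n_aug: int = 1,
) -> WorthState:
    """Fast-path update taking pre-flattened stage terms (or None for no data)."""
    if n_aug < 1:
        raise ValueError("n_aug must be >= 1")
    for _ in range(n_aug):
        state = _gibbs_sweep_terms(state, terms, hyper, rng)
    return state


def worth_gibbs_update(
    state: WorthState,
    data: RankingDataset | None,
    hyper: Hyperparams,
    rng: np.random.Generator,
    n_aug: int = 1,
) -> WorthState:
    """Update cluster worths by ``n_aug`` augmentation + Gamma-draw sweeps.

    The partition is left untouched; with no data the draw is from the
    Gamma(a, b) prior, so the prior is exactly preserved.
    """
    terms = None if data is None or len(data) == 0 else _terms_of(data)
    return worth_gibbs_update_terms(state, terms, hyper, rng, n_aug)
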
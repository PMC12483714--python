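"""Exact posterior over partitions for small object sets.

For J up to ~7 the posterior P(g | data) can be computed without MCMC:
enumerate every partition, integrate the BTL likelihood over the Gamma
slab worths by tensor-product Gauss-Laguerre quadrature, and weight by
the partition prior. Used as an independent check of the reversible-jump
sampler and available for small exact analyses.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.laguerre import laggauss
from scipy.special import gammaln, logsumexp

from .datamodel import Hyperparams, Partition, RankingDataset, enumerate_partitions
from .likelihood import LogLikTerms
from .prior import partition_log_prior

__all__ = ["exact_partition_posterior", "log_marginal_likelihood"]

_MAX_J = 7


def log_marginal_likelihood(
    g: Partition,
    terms: LogLikTerms,
    hyper: Hyperparams,
    n_nodes: int = 48,
) -> float:
    """log integral of the BTL likelihood over Gamma(a, b) cluster worths.

    Substituting x = b * lambda maps the integral onto the Gauss-Laguerre
    weight exp(-x); nodes are tensorized over the K cluster dimensions.
    """
    K = g.n_clusters
    x, wq = laggauss(n_nodes)
    grids = np.meshgrid(*([x] * K), indexing="ij")
    xs = np.stack([grid.ravel() for grid in grids])          # (K, G)
    lam = xs[np.asarray(g.assignment)] / hyper.b             # (J, G)
    ll = terms.win_counts @ np.log(lam) - np.log(terms.remaining @ lam).sum(axis=0)
    # Gamma(a, b) density against the e^{-x} weight: x^{a-1} / Gamma(a)
    log_density = ((hyper.a - 1.0) * np.log(xs) - gammaln(hyper.a)).sum(axis=0)
    lw = np.meshgrid(*([np.log(wq)] * K), indexing="ij")
    log_weights = np.stack([g_.ravel() for g_ in lw]).sum(axis=0)
    return float(logsumexp(ll + log_density + log_weights))


def exact_partition_posterior(
    data: RankingDataset,
    hyper: Hyperparams,
    n_nodes: int = 48,
) -> tuple[list[Partition], np.ndarray]:
    """Posterior probabilities of every partition by direct integration."""
    J = data.n_objects
    if J > _MAX_J:
        raise ValueError(f"exact posterior supported for J <= {_MAX_J}")
    terms = LogLikTerms.from_dataset(data)
    parts = enumerate_partitions(J)
    logpost = np.array(
        [
            partition_log_prior(g, hyper.nu)
            + log_marginal_likelihood(g, terms, hyper, n_nodes)
            for g in parts
        ]
    )
    post = np.exp(logpost - logpost.max())
    return parts, post / post.sum()
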
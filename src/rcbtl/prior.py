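"""Partition-based spike-and-slab fusion (PSSF) prior on worth parameters.

The prior draws a set partition ``g`` of the J objects, then one worth per
cluster i.i.d. from a Gamma(a, b) slab, and broadcasts cluster worths to
objects. The partition prior places mass on each individual partition
proportional to a Poisson(nu) pmf evaluated at its number of clusters K and
truncated to {1..J}: every partition with the same K is equally likely, so
the induced marginal on K is proportional to f(K) * S(J, K), with S the
Stirling number of the second kind.

The "spike" of the prior is the event that two objects share a cluster
(their worths are exactly equal); the "slab" is the Gamma law of distinct
cluster worths. Regardless of the partition prior, each object's marginal
worth distribution is exactly Gamma(a, b).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import gamma as gamma_dist

from .datamodel import Hyperparams, Partition, WorthState, enumerate_partitions

__all__ = [
    "truncated_poisson_log_pmf",
    "partition_log_prior",
    "worth_log_prior",
    "sample_partition",
    "sample_prior",
    "prior_spike_mass",
    "prior_k_pmf",
    "stirling2",
]


@lru_cache(maxsize=None)
def stirling2(n: int, k: int) -> int:
    """Stirling number of the second kind, S(n, k), exact."""
    if n == k:
        return 1
    if k == 0 or k > n:
        return 0
    return k * stirling2(n - 1, k) + stirling2(n - 1, k - 1)


def truncated_poisson_log_pmf(k, nu: float, J: int) -> np.ndarray:
    """log f(k; nu): Poisson(nu) pmf truncated and renormalized to {1..J}."""
    if nu <= 0:
        raise ValueError("nu must be positive")
    ks = np.arange(1, J + 1)
    logp = ks * np.log(nu) - gammaln(ks + 1)
    logp -= logsumexp(logp)
    k = np.asarray(k)
    if np.any((k < 1) | (k > J)):
        raise ValueError(f"K must lie in 1..{J}")
    return logp[k - 1]


def partition_log_prior(g: Partition, nu: float) -> float:
    """Log prior mass of one partition, up to the constant sum_g f(K(g)).

    Equal for any two partitions with the same number of clusters; only
    ratios enter the Metropolis-Hastings acceptance probability, so the
    partition-sum normalizer (intractable for large J) is omitted. The
    exactly normalized pmf is available for small J via
    :func:`prior_partition_pmf`.
    """
    return float(truncated_poisson_log_pmf(g.n_clusters, nu, g.n_objects))


def worth_log_prior(cluster_worths, a: float, b: float) -> float:
    """Joint log-density of i.i.d. Gamma(shape=a, rate=b) cluster worths."""
    w = np.asarray(cluster_worths, dtype=float)
    if np.any(w <= 0):
        raise ValueError("worths must be strictly positive")
    return float(gamma_dist.logpdf(w, a, scale=1.0 / b).sum())


def prior_k_pmf(J: int, nu: float) -> np.ndarray:
    """Exact prior pmf of K: proportional to f(K; nu) * S(J, K), K = 1..J."""
    logf = truncated_poisson_log_pmf(np.arange(1, J + 1), nu, J)
    logS = np.array([float(np.log(stirling2(J, k))) for k in range(1, J + 1)])
    logw = logf + logS
    return np.exp(logw - logsumexp(logw))


def prior_partition_pmf(J: int, nu: float) -> tuple[list[Partition], np.ndarray]:
    """Exactly normalized prior over all partitions (small J only)."""
    parts = enumerate_partitions(J)
    logw = np.array([partition_log_prior(g, nu) for g in parts])
    return parts, np.exp(logw - logsumexp(logw))


def sample_partition(J: int, nu: float, rng: np.random.Generator) -> Partition:
    """Draw a partition from the prior.

    Samples K from its Stirling-weighted marginal, then a uniform partition
    with exactly K blocks via the standard S(n, k) recursive construction
    (last object is a singleton with probability S(n-1, k-1) / S(n, k),
    otherwise it joins one of the k blocks of a uniform (n-1, k) partition).
    """
    K = int(rng.choice(np.arange(1, J + 1), p=prior_k_pmf(J, nu)))
    # build uniform partition of {0..J-1} into K blocks, back to front
    singleton = np.zeros(J + 1, dtype=bool)
    n, k = J, K
    while n > 0:
        p_single = stirling2(n - 1, k - 1) / stirling2(n, k) if k >= 1 else 0.0
        if k == n or rng.uniform() < p_single:
            singleton[n] = True
            k -= 1
        n -= 1
    assignment = np.empty(J, dtype=int)
    n_open = 0
    for j in range(J):
        if singleton[j + 1]:
            assignment[j] = n_open
            n_open += 1
        else:
            assignment[j] = int(rng.integers(n_open))
    return Partition(assignment)


def sample_prior(J: int, hyper: Hyperparams, rng: np.random.Generator) -> WorthState:
    """Draw (partition, cluster worths) from the PSSF prior."""
    g = sample_partition(J, hyper.nu, rng)
    while True:
        worths = rng.gamma(hyper.a, 1.0 / hyper.b, size=g.n_clusters)
        if len(np.unique(worths)) == g.n_clusters:  # ties have probability 0
            return WorthState(g, worths)


def prior_spike_mass(j: int, jp: int, hyper: Hyperparams, J: int) -> float:
    """P(objects j and j' share a cluster) under the partition prior.

    Exact for any J: partitions of J objects into K blocks with j and j'
    together biject with partitions of J-1 objects into K blocks, so the
    spike mass is  sum_K f(K) S(J-1, K) / sum_K f(K) S(J, K). Independent
    of which pair (j, j') by exchangeability.
    """
    if j == jp:
        raise ValueError("spike mass requires two distinct objects")
    if not (0 <= j < J and 0 <= jp < J):
        raise ValueError("object index out of range")
    logf = truncated_poisson_log_pmf(np.arange(1, J + 1), hyper.nu, J)
    log_top = [
        logf[k - 1] + np.log(stirling2(J - 1, k))
        for k in range(1, J)
        if stirling2(J - 1, k) > 0
    ]
    log_bot = [logf[k - 1] + np.log(stirling2(J, k)) for k in range(1, J + 1)]
    return float(np.exp(logsumexp(log_top) - logsumexp(log_bot)))
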
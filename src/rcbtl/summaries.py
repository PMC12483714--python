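"""Posterior summaries: normalization, rank-cluster summaries, fit checks.

Worths are identifiable only up to scale, so all reporting happens after
post-hoc normalization of each posterior draw to sum to one, which makes a
worth readable as the probability of being the first choice out of all J
objects. Rank-cluster structure is summarized by the posterior
co-clustering matrix (pairwise probabilities of shared rank) and by the
maximum a posteriori partition; model adequacy by a posterior predictive
p-value on pairwise win counts.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import Partition, RankingDataset

__all__ = [
    "ChainSamples",
    "normalize_worths",
    "cocluster_matrix",
    "map_clustering",
    "k_credible_interval",
    "rank_point_estimates",
    "pairwise_beat_counts",
    "posterior_predictive_pvalue",
    "mae",
]


@dataclass
class ChainSamples:
    """Per-iteration MCMC records of (partition, worths).

    ``assignments[t]`` is the canonical cluster assignment at iteration t,
    ``worths[t]`` the expanded length-J worth vector, ``k_trace[t]`` the
    number of clusters. The first half of the chain is treated as burn-in
    wherever a burn-in is not given explicitly.
    """

    assignments: np.ndarray  # (n, J) int
    worths: np.ndarray       # (n, J) float
    k_trace: np.ndarray      # (n,) int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, J = self.assignments.shape
        if self.worths.shape != (n, J) or self.k_trace.shape != (n,):
            raise ValueError("assignments, worths and k_trace lengths disagree")
        if not np.array_equal(self.k_trace, self.assignments.max(axis=1) + 1):
            raise ValueError("k_trace inconsistent with assignments")

    @property
    def n_iterations(self) -> int:
        return self.assignments.shape[0]

    @property
    def n_objects(self) -> int:
        return self.assignments.shape[1]

    def default_burnin(self) -> int:
        return self.n_iterations // 2

    def _start(self, burnin: Optional[int]) -> int:
        start = self.default_burnin() if burnin is None else int(burnin)
        if not 0 <= start < self.n_iterations:
            raise ValueError(
                f"burn-in {start} leaves no samples out of {self.n_iterations}"
            )
        return start

    def retained_assignments(self, burnin: Optional[int] = None) -> np.ndarray:
        return self.assignments[self._start(burnin):]

    def retained_worths(self, burnin: Optional[int] = None) -> np.ndarray:
        return self.worths[self._start(burnin):]

    def retained_k(self, burnin: Optional[int] = None) -> np.ndarray:
        return self.k_trace[self._start(burnin):]


def normalize_worths(samples):
    """Rescale each draw's worth vector to sum to 1.

    Accepts an (n, J) array or a :class:`ChainSamples` (returning the same
    kind). Rescaling preserves worth ratios, hence all choice probabilities
    and the co-clustering pattern.
    """
    if isinstance(samples, ChainSamples):
        return ChainSamples(
            assignments=samples.assignments,
            worths=normalize_worths(samples.worths),
            k_trace=samples.k_trace,
            meta=dict(samples.meta),
        )
    w = np.asarray(samples, dtype=float)
    if np.any(w <= 0):
        raise ValueError("worths must be strictly positive")
    return w / w.sum(axis=-1, keepdims=True)


def cocluster_matrix(samples: ChainSamples, burnin: Optional[int] = None) -> np.ndarray:
    """J x J posterior probabilities that object pairs share a rank-cluster.

    Entry (i, j) is the fraction of retained iterations with g_i = g_j;
    symmetric with unit diagonal.
    """
    a = samples.retained_assignments(burnin)
    same = a[:, :, None] == a[:, None, :]
    return same.mean(axis=0)


def map_clustering(samples: ChainSamples, burnin: Optional[int] = None) -> Partition:
    """Modal canonical partition of the retained samples.

    Ties in visit counts are broken by earliest first occurrence, with a
    warning.
    """
    a = samples.retained_assignments(burnin)
    keys = [tuple(int(x) for x in row) for row in a]
    counts = Counter(keys)
    top = max(counts.values())
    modal = [k for k, c in counts.items() if c == top]
    if len(modal) > 1:
        warnings.warn(
            f"{len(modal)} partitions tie at {top} visits; "
            "returning the earliest seen",
            stacklevel=2,
        )
        for key in keys:
            if key in modal:
                return Partition(key)
    return Partition(modal[0])


def k_credible_interval(
    samples: ChainSamples, level: float, burnin: Optional[int] = None
) -> tuple[int, int]:
    """Equal-tailed credible interval for the number of rank-clusters.

    Quantiles are empirical order statistics (inverse-CDF convention), so
    the endpoints are attained K values.
    """
    if not 0.0 < level <= 1.0:
        raise ValueError("level must lie in (0, 1]")
    k = np.sort(samples.retained_k(burnin))
    alpha = 1.0 - level
    lo = k[_order_stat_index(alpha / 2.0, len(k))]
    hi = k[_order_stat_index(1.0 - alpha / 2.0, len(k))]
    return int(lo), int(hi)


def _order_stat_index(q: float, n: int) -> int:
    return min(max(int(np.ceil(q * n)) - 1, 0), n - 1)


def rank_point_estimates(
    samples: ChainSamples,
    burnin: Optional[int] = None,
    labels: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Objects ordered by posterior median normalized worth, with tiers.

    Returns one row per object: label, posterior median normalized worth,
    rank (1 = most preferred) and the tier (rank-cluster) it belongs to in
    the maximum a posteriori partition.
    """
    w = normalize_worths(samples.retained_worths(burnin))
    med = np.median(w, axis=0)
    J = samples.n_objects
    if labels is None:
        labels = [f"obj{j + 1}" for j in range(J)]
    g = map_clustering(samples, burnin)
    order = np.argsort(-med, kind="stable")
    rank = np.empty(J, dtype=int)
    rank[order] = np.arange(1, J + 1)
    return pd.DataFrame(
        {
            "object": labels,
            "median_worth": med,
            "rank": rank,
            "tier": list(g.assignment),
        }
    ).sort_values("rank", ignore_index=True)


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


def _design_arrays(data: RankingDataset):
    """Considered mask (I, J), ranked counts (I,), observed positions (I, J)."""
    I, J = len(data), data.n_objects
    cons = np.zeros((I, J), dtype=bool)
    n_ranked = np.zeros(I, dtype=int)
    pos = np.full((I, J), J, dtype=int)  # J == "unranked"
    for i, obs in enumerate(data):
        cons[i, list(obs.considered)] = True
        n_ranked[i] = obs.n_ranked
        for s, j in enumerate(obs.ranked):
            pos[i, j] = s
    return cons, n_ranked, pos


def _beat_counts(cons: np.ndarray, n_ranked: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """counts[j, j'] = #observations in which j beats j'.

    j beats j' when both are considered, j is ranked, and j' is either
    ranked later or left unranked.
    """
    ranked = cons & (pos < n_ranked[:, None])
    beats = ranked[:, :, None] & cons[:, None, :] & (pos[:, :, None] < pos[:, None, :])
    return beats.sum(axis=0).astype(float)


def pairwise_beat_counts(data: RankingDataset) -> np.ndarray:
    """Observed pairwise win-count matrix n_{jj'} of a dataset."""
    return _beat_counts(*_design_arrays(data))


def _simulate_beat_counts(cons, n_ranked, logw, rng) -> np.ndarray:
    """Beat counts of one replicate dataset with the same design.

    Sequential worth-proportional ranking is realized as log-worths plus
    i.i.d. Gumbel noise, sorted within each judge's considered set.
    """
    I, J = cons.shape
    scores = np.where(cons, logw[None, :] + rng.gumbel(size=(I, J)), -np.inf)
    order = np.argsort(-scores, axis=1)
    pos = np.empty_like(order)
    np.put_along_axis(pos, order, np.arange(J)[None, :], axis=1)
    pos = np.where(cons, pos, J)
    return _beat_counts(cons, n_ranked, pos)


def posterior_predictive_pvalue(
    samples: ChainSamples,
    data: RankingDataset,
    rng: np.random.Generator | int | None = None,
    n_rep: int = 100,
    n_expected: int = 10,
    burnin: Optional[int] = None,
    eps: float = 1e-8,
) -> float:
    """Posterior predictive p-value of a pairwise-wins discrepancy.

    For each of ``n_rep`` retained posterior draws (evenly spaced), a
    replicate dataset with the observed design (same considered sets and
    ranked lengths) is simulated and the chi-square-style discrepancy

        D(x; lambda) = sum_{j != j'} (n_{jj'}(x) - e_{jj'})^2 / max(e_{jj'}, eps)

    is evaluated for the replicate and for the observed data, with the
    expected counts ``e`` estimated by ``n_expected`` Monte-Carlo
    replicates under the same draw. The p-value is the fraction of draws
    whose replicate discrepancy is at least the observed one; values near
    0.5 indicate adequate fit, values near 0 misfit.
    """
    if n_rep < 1 or n_expected < 1:
        raise ValueError("n_rep and n_expected must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cons, n_ranked, pos = _design_arrays(data)
    n_obs = _beat_counts(cons, n_ranked, pos)
    w = samples.retained_worths(burnin)
    idx = np.linspace(0, len(w) - 1, num=min(n_rep, len(w))).astype(int)
    off_diag = ~np.eye(data.n_objects, dtype=bool)

    exceed = 0
    for t in idx:
        logw = np.log(w[t])
        sims = np.stack(
            [_simulate_beat_counts(cons, n_ranked, logw, rng) for _ in range(n_expected + 1)]
        )
        e = sims[:-1].mean(axis=0)
        denom = np.maximum(e, eps)
        d_obs = (((n_obs - e) ** 2 / denom)[off_diag]).sum()
        d_rep = (((sims[-1] - e) ** 2 / denom)[off_diag]).sum()
        exceed += d_rep >= d_obs
    return exceed / len(idx)


def mae(estimate, truth) -> float:
    """Mean absolute error between two normalized worth vectors."""
    est = np.asarray(estimate, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {tru.shape}")
    return float(np.abs(est - tru).mean())
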
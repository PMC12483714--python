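"""Reversible-jump birth/death sampler over (partition, cluster worths).

The partition of objects into rank-clusters is updated by dimension-changing
Metropolis-Hastings moves in the style of Green's reversible-jump MCMC:

* **birth** — a cluster with at least two members is chosen uniformly and
  split "binomially" (each member goes independently to one of two children,
  conditional on both children being nonempty); the cluster's worth ``lam``
  is split into two child worths through a bijection driven by an auxiliary
  ``u ~ Uniform(0, 1)``;
* **death** — one of the ``K - 1`` *adjacent* cluster pairs (consecutive in
  the sorted order of cluster worths) is chosen uniformly and merged, the
  merged worth solving the split equations exactly.

Births whose two children are not adjacent in the new worth ordering are
automatically rejected: a death can only merge adjacent clusters, so
reversibility requires births to create only adjacent pairs. Since every
partition has positive prior probability and any partition can be reached
by successive births and deaths, the chain is irreducible; within-K
shuffle moves are unnecessary.

The full sampler alternates a birth/death partition step with the
closed-form augmented Gibbs update of the cluster worths
(:mod:`rcbtl.gibbs`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import Hyperparams, Partition, RankingDataset, WorthState
from .gibbs import worth_gibbs_update_terms
from .likelihood import LogLikTerms
from .prior import truncated_poisson_log_pmf, worth_log_prior
from .summaries import ChainSamples

__all__ = [
    "SplitMergeBijection",
    "MEAN_PRESERVING_SPLIT",
    "MoveProposal",
    "birth_prob",
    "death_prob",
    "propose_birth",
    "propose_death",
    "acceptance_log_ratio",
    "partition_step",
    "run_chain",
]


@dataclass(frozen=True)
class SplitMergeBijection:
    """The worth-space bijection (lam, u) <-> (lam1, lam2) used by birth/death.

    The default is the arithmetic-mean-preserving split

        lam1 = 2 * lam * u,   lam2 = 2 * lam * (1 - u),   u ~ Uniform(0, 1),

    whose inverse is lam = (lam1 + lam2) / 2, u = lam1 / (lam1 + lam2) and
    whose Jacobian |d(lam1, lam2) / d(lam, u)| = 4 * lam. The acceptance
    ratio consumes (split, merge, Jacobian, density of u) as one object, so
    an alternative bijection is a drop-in replacement.
    """

    def split(self, lam: float, u: float) -> tuple[float, float]:
        return 2.0 * lam * u, 2.0 * lam * (1.0 - u)

    def merge(self, lam1: float, lam2: float) -> tuple[float, float]:
        return 0.5 * (lam1 + lam2), lam1 / (lam1 + lam2)

    def log_jacobian(self, lam: float, u: float) -> float:
        return float(np.log(4.0 * lam))

    def sample_u(self, rng: np.random.Generator) -> float:
        return float(rng.uniform())

    def log_q(self, u: float) -> float:
        return 0.0


MEAN_PRESERVING_SPLIT = SplitMergeBijection()


def birth_prob(K: int, J: int) -> float:
    """Probability of attempting a birth at K clusters (b_1=1, b_J=0, else 1/2)."""
    if J == 1:
        return 0.0
    if K == 1:
        return 1.0
    if K == J:
        return 0.0
    return 0.5


def death_prob(K: int, J: int) -> float:
    return 0.0 if J == 1 else 1.0 - birth_prob(K, J)


@dataclass(frozen=True)
class MoveProposal:
    """A birth or death proposal with its bookkeeping terms.

    ``log_proposal_ratio`` is log q(reverse move) - log q(this move) and
    ``log_jacobian`` the log |Jacobian| of the worth-space map; both enter
    the acceptance ratio additively.
    """

    kind: str  # "birth" | "death"
    new_state: WorthState
    log_proposal_ratio: float
    log_jacobian: float
    u: Optional[float] = None


def _state_from_expanded(assignment: np.ndarray, expanded: np.ndarray) -> WorthState:
    g = Partition(_relabel(assignment))
    cw = [0.0] * g.n_clusters
    for j, k in enumerate(g.assignment):
        cw[k] = float(expanded[j])
    return WorthState(g, cw)


def _relabel(raw: np.ndarray) -> list[int]:
    seen: dict[int, int] = {}
    out = []
    for k in raw:
        k = int(k)
        if k not in seen:
            seen[k] = len(seen)
        out.append(seen[k])
    return out


def _n_eligible(sizes) -> int:
    return sum(1 for s in sizes if s >= 2)


def propose_birth(
    state: WorthState,
    rng: np.random.Generator,
    bijection: SplitMergeBijection = MEAN_PRESERVING_SPLIT,
) -> Optional[MoveProposal]:
    """Propose splitting one multi-object cluster into two adjacent children.

    Returns ``None`` when the move is unavailable (no cluster has two or
    more members) or auto-rejected (children not adjacent in worth order,
    or a zero-probability worth tie); both count as rejections.
    """
    g = state.partition
    J, K = g.n_objects, g.n_clusters
    sizes = g.cluster_sizes
    eligible = [k for k in range(K) if sizes[k] >= 2]
    if not eligible:
        return None
    k = eligible[int(rng.integers(len(eligible)))]
    members = g.cluster_members[k]
    N = len(members)
    while True:  # binomial split conditional on both children nonempty
        bits = rng.integers(0, 2, size=N)
        if 0 < bits.sum() < N:
            break
    u = bijection.sample_u(rng)
    lam = state.cluster_worths[k]
    lam1, lam2 = bijection.split(lam, u)
    others = [w for kk, w in enumerate(state.cluster_worths) if kk != k]
    lo, hi = min(lam1, lam2), max(lam1, lam2)
    if lam1 == lam2 or any(w == lam1 or w == lam2 for w in others):
        return None  # zero-probability tie; reject to keep worths distinct
    if any(lo < w < hi for w in others):
        return None  # children not adjacent: auto-reject for reversibility

    new_assignment = np.asarray(g.assignment).copy()
    expanded = np.asarray(state.expanded_worths, dtype=float)
    for m, bit in zip(members, bits):
        new_assignment[m] = K if bit else k
        expanded[m] = lam2 if bit else lam1
    new_state = _state_from_expanded(new_assignment, expanded)

    n_splits = 2 ** (N - 1) - 1  # unordered nonempty two-way splits of N objects
    log_prop = (
        np.log(death_prob(K + 1, J))
        - np.log(K)  # adjacent pairs after the split
        - np.log(birth_prob(K, J))
        + np.log(len(eligible))
        + np.log(n_splits)
        - bijection.log_q(u)
    )
    return MoveProposal(
        kind="birth",
        new_state=new_state,
        log_proposal_ratio=float(log_prop),
        log_jacobian=bijection.log_jacobian(lam, u),
        u=u,
    )


def propose_death(
    state: WorthState,
    rng: np.random.Generator,
    bijection: SplitMergeBijection = MEAN_PRESERVING_SPLIT,
) -> Optional[MoveProposal]:
    """Propose merging one uniformly chosen adjacent pair of clusters.

    Returns ``None`` when K = 1 (no pair to merge). The proposal terms are
    the exact reciprocals of the reverse birth's, so an accepted death
    followed by the matching birth restores the state bit-for-bit.
    """
    g = state.partition
    J, K = g.n_objects, g.n_clusters
    if K == 1:
        return None
    order = np.argsort(state.cluster_worths)
    p = int(rng.integers(K - 1))
    ka, kb = int(order[p]), int(order[p + 1])
    lam1, lam2 = state.cluster_worths[ka], state.cluster_worths[kb]
    lam, u = bijection.merge(lam1, lam2)

    assignment = np.asarray(g.assignment)
    expanded = np.asarray(state.expanded_worths, dtype=float)
    new_assignment = np.where(assignment == kb, ka, assignment)
    merged_members = np.isin(assignment, (ka, kb))
    expanded[merged_members] = lam
    new_state = _state_from_expanded(new_assignment, expanded)

    N = int(merged_members.sum())
    n_elig_merged = _n_eligible(new_state.partition.cluster_sizes)
    n_splits = 2 ** (N - 1) - 1
    log_prop = -(
        np.log(death_prob(K, J))
        - np.log(K - 1)
        - np.log(birth_prob(K - 1, J))
        + np.log(n_elig_merged)
        + np.log(n_splits)
        - bijection.log_q(u)
    )
    return MoveProposal(
        kind="death",
        new_state=new_state,
        log_proposal_ratio=float(log_prop),
        log_jacobian=-bijection.log_jacobian(lam, u),
        u=u,
    )


def _as_terms(data) -> Optional[LogLikTerms]:
    if data is None:
        return None
    if isinstance(data, LogLikTerms):
        return data if data.n_stages else None
    if isinstance(data, RankingDataset):
        return _as_terms(LogLikTerms.from_dataset(data))
    raise TypeError(f"expected RankingDataset, LogLikTerms or None, got {type(data)}")


def acceptance_log_ratio(
    current: WorthState,
    proposal: MoveProposal,
    data,
    hyper: Hyperparams,
) -> float:
    """Log Metropolis-Hastings ratio for a birth/death proposal.

    Sum of the data log-likelihood difference, the partition-prior and
    worth-prior differences, the proposal ratio and the log-Jacobian. The
    move is accepted with probability min(1, exp(value)); the ratio of the
    matching reverse move is the exact negative.
    """
    terms = _as_terms(data)
    new = proposal.new_state
    J = current.partition.n_objects
    delta = 0.0
    if terms is not None:
        w_cur = np.asarray(current.expanded_worths)
        w_new = np.asarray(new.expanded_worths)
        delta += terms.loglik(w_new) - terms.loglik(w_cur)
    delta += float(
        truncated_poisson_log_pmf(new.partition.n_clusters, hyper.nu, J)
        - truncated_poisson_log_pmf(current.partition.n_clusters, hyper.nu, J)
    )
    delta += worth_log_prior(new.cluster_worths, hyper.a, hyper.b) - worth_log_prior(
        current.cluster_worths, hyper.a, hyper.b
    )
    return float(delta + proposal.log_proposal_ratio + proposal.log_jacobian)


def partition_step(
    state: WorthState,
    data,
    hyper: Hyperparams,
    rng: np.random.Generator,
    bijection: SplitMergeBijection = MEAN_PRESERVING_SPLIT,
) -> tuple[WorthState, bool]:
    """One birth/death update of (partition, worths).

    A birth is attempted with probability ``b_K`` and a death otherwise;
    unavailable or auto-rejected moves count as rejections. Returns the
    (possibly unchanged) state and whether a move was accepted.
    """
    J = state.partition.n_objects
    K = state.n_clusters
    bk = birth_prob(K, J)
    if bk == 0.0 and death_prob(K, J) == 0.0:
        return state, False
    do_birth = rng.uniform() < bk
    proposal = (
        propose_birth(state, rng, bijection)
        if do_birth
        else propose_death(state, rng, bijection)
    )
    if proposal is None:
        return state, False
    log_a = acceptance_log_ratio(state, proposal, data, hyper)
    if np.log(rng.uniform()) < log_a:
        return proposal.new_state, True
    return state, False


def initial_state(J: int, hyper: Hyperparams, rng: np.random.Generator) -> WorthState:
    """All-singleton start with i.i.d. Gamma(a, b) worths.

    Starting from K = J lets rank-clusters form during estimation rather
    than being imposed at initialization.
    """
    while True:
        worths = rng.gamma(hyper.a, 1.0 / hyper.b, size=J)
        if len(np.unique(worths)) == J:
            return WorthState(Partition(range(J)), worths)


def run_chain(
    data,
    hyper: Hyperparams,
    n_iters: int,
    n_aug: int = 1,
    rng: np.random.Generator | int | None = None,
    init: WorthState | None = None,
    bijection: SplitMergeBijection = MEAN_PRESERVING_SPLIT,
) -> ChainSamples:
    """Run the alternating birth/death + augmented-Gibbs sampler.

    Parameters
    ----------
    data
        A :class:`~rcbtl.datamodel.RankingDataset` (possibly with zero
        observations) or ``None``; with no data the chain targets the
        prior, which is the standard correctness battery for the sampler.
    hyper
        Poisson rate ``nu`` on K and Gamma ``(a, b)`` slab.
    n_iters
        Number of recorded iterations, each one partition step followed by
        ``n_aug`` augmented Gibbs sweeps of the cluster worths.
    rng
        Seed or generator; a fixed seed reproduces the sample path exactly.
    init
        Starting state; defaults to all singletons with prior-drawn worths.

    Returns
    -------
    ChainSamples
        Per-iteration canonical partitions, expanded worths and K, plus
        run metadata (a half-chain burn-in is the downstream default).
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    terms = _as_terms(data)
    if isinstance(data, RankingDataset):
        J = data.n_objects
    elif isinstance(data, LogLikTerms):
        J = data.n_objects
    elif init is not None:
        J = init.partition.n_objects
    else:
        raise ValueError("with data=None an explicit init (or dataset) is required")
    state = init if init is not None else initial_state(J, hyper, rng)

    assignments = np.empty((n_iters, J), dtype=np.int32)
    worths = np.empty((n_iters, J), dtype=float)
    k_trace = np.empty(n_iters, dtype=np.int32)
    n_accepted = 0
    for t in range(n_iters):
        state, accepted = partition_step(state, terms, hyper, rng, bijection)
        n_accepted += accepted
        state = worth_gibbs_update_terms(state, terms, hyper, rng, n_aug)
        assignments[t] = state.partition.assignment
        worths[t] = state.expanded_worths
        k_trace[t] = state.n_clusters
    return ChainSamples(
        assignments=assignments,
        worths=worths,
        k_trace=k_trace,
        meta={
            "hyper": {"nu": hyper.nu, "a": hyper.a, "b": hyper.b},
            "n_iters": n_iters,
            "n_aug": n_aug,
            "acceptance_rate": n_accepted / n_iters,
        },
    )
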
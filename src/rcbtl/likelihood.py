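"""Bradley-Terry-Luce likelihood for mixed complete/partial/incomplete rankings.

A judge builds an observed ranking sequentially: at each stage one object is
chosen from the remaining considered objects with probability proportional
to its worth. The probability of an observed prefix pi over considered set S
is therefore

    P(pi | lambda) = prod_s  lambda_{pi(s)} / sum_{j in remaining_s} lambda_j

where ``remaining_s`` is S minus the s-1 objects already chosen. The final
stage of a complete ranking (one object left) has probability 1 and is
never iterated. Choice probabilities depend only on worth *ratios*, so the
likelihood is invariant to rescaling all worths by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .datamodel import RankingDataset, RankingObservation

__all__ = [
    "LogLikTerms",
    "observation_loglik",
    "dataset_loglik",
    "pairwise_prob",
    "sample_ranking",
]


@dataclass(frozen=True)
class LogLikTerms:
    """Flattened per-stage likelihood terms for a dataset.

    Every non-trivial selection stage across all judges becomes one row:
    ``winner[t]`` is the object chosen at stage ``t`` and ``remaining[t]``
    is the 0/1 indicator row of the objects still available (the stage's
    denominator set, which always contains the winner). Stages with a
    single remaining object carry no information and are dropped.

    ``win_counts[j]`` caches how many stages object ``j`` wins, so the
    numerator of the log-likelihood is a dot product.
    """

    n_objects: int
    winner: np.ndarray      # (T,) int64
    remaining: np.ndarray   # (T, J) float64 in {0, 1}
    win_counts: np.ndarray  # (J,) float64

    @classmethod
    def from_dataset(cls, data: RankingDataset) -> "LogLikTerms":
        J = data.n_objects
        winners: list[int] = []
        rows: list[np.ndarray] = []
        for obs in data.observations:
            left = np.zeros(J)
            left[list(obs.considered)] = 1.0
            n_stages = min(obs.n_ranked, obs.n_considered - 1)
            for s in range(n_stages):
                winners.append(obs.ranked[s])
                rows.append(left.copy())
                left[obs.ranked[s]] = 0.0
        winner = np.asarray(winners, dtype=np.int64)
        remaining = (
            np.asarray(rows) if rows else np.zeros((0, J))
        )
        win_counts = np.bincount(winner, minlength=J).astype(float)
        return cls(J, winner, remaining, win_counts)

    @property
    def n_stages(self) -> int:
        return len(self.winner)

    def loglik(self, worths: np.ndarray) -> float:
        """Dataset log-likelihood at a positive worth vector."""
        worths = _check_worths(worths, self.n_objects)
        if self.n_stages == 0:
            return 0.0
        denom = self.remaining @ worths
        return float(self.win_counts @ np.log(worths) - np.log(denom).sum())


def _check_worths(worths, J: int) -> np.ndarray:
    w = np.asarray(worths, dtype=float)
    if w.shape != (J,):
        raise ValueError(f"expected {J} worths, got shape {w.shape}")
    if not np.all(w > 0) or not np.all(np.isfinite(w)):
        raise ValueError("worths must be finite and strictly positive")
    return w


def observation_loglik(obs: RankingObservation, worths) -> float:
    """Log-probability of one observed ranking under BTL worths.

    Uses a log-sum-exp guard on each stage denominator so that extreme
    worth ratios do not overflow.
    """
    J = max(obs.considered) + 1
    w = np.asarray(worths, dtype=float)
    if np.any(w[list(obs.considered)] <= 0):
        raise ValueError("worths must be strictly positive")
    logw = np.log(w)
    remaining = sorted(obs.considered)
    total = 0.0
    n_stages = min(obs.n_ranked, obs.n_considered - 1)
    for s in range(n_stages):
        j = obs.ranked[s]
        total += logw[j] - logsumexp(logw[remaining])
        remaining.remove(j)
    return float(total)


def dataset_loglik(data: RankingDataset, worths) -> float:
    """Sum of observation log-likelihoods over all judges (exchangeable)."""
    return LogLikTerms.from_dataset(data).loglik(
        _check_worths(worths, data.n_objects)
    )


def pairwise_prob(i: int, j: int, worths) -> float:
    """P(object i beats object j in a pairwise tournament) = li / (li + lj)."""
    if i == j:
        raise ValueError("pairwise probability requires two distinct objects")
    w = np.asarray(worths, dtype=float)
    if w[i] <= 0 or w[j] <= 0:
        raise ValueError("worths must be strictly positive")
    return float(w[i] / (w[i] + w[j]))


def sample_ranking(
    considered,
    n_ranked: int,
    worths,
    rng: np.random.Generator,
) -> RankingObservation:
    """Draw a (possibly partial) ranking by sequential worth-proportional choice.

    Equivalent to perturbing log-worths with i.i.d. Gumbel noise and sorting
    (used here for vectorization-friendliness); stage-1 choice frequencies
    converge to ``worths / sum(worths)`` over the considered set.
    """
    considered = sorted(int(j) for j in considered)
    if not 1 <= n_ranked <= len(considered):
        raise ValueError(f"need 1 <= n_ranked <= {len(considered)}, got {n_ranked}")
    w = np.asarray(worths, dtype=float)[considered]
    if np.any(w <= 0):
        raise ValueError("worths must be strictly positive")
    scores = np.log(w) + rng.gumbel(size=len(considered))
    order = np.argsort(-scores)
    ranked = [considered[o] for o in order[:n_ranked]]
    return RankingObservation(ranked, considered)
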
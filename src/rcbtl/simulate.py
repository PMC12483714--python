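"""Synthetic ordinal data from the model's own generative process.

The study design places J objects into K equal-sized true rank-clusters
whose worths form the geometric sequence 1, 4, 16, ...: a fourfold worth
step makes the better object of an adjacent pair win a pairwise tournament
with probability 4/(1+4) = 0.8 — strong but not absolute separation. Each
judge considers a uniformly random size-S subset of the objects and ranks
the top R of them sequentially; (R, S) spans complete (R = S = J), partial
(R < S) and pairwise (R = 1, S = 2) regimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import Hyperparams, Partition, RankingDataset, RankingObservation
from .likelihood import sample_ranking

__all__ = ["make_true_worths", "generate_dataset", "ExperimentGrid", "run_experiment"]


def make_true_worths(
    J: int, K: int, *, k1_means_singletons: bool = True
) -> tuple[np.ndarray, Partition]:
    """True worth vector and partition with K rank-clusters of size J/K.

    Cluster worths are 4**0, 4**1, ..., 4**(K-1), assigned blockwise: the
    first J/K objects share the lowest worth, the last J/K the highest.

    ``k1_means_singletons`` selects the reading of K = 1 in which every
    object is independent (all singleton rank-clusters, worths
    4**0..4**(J-1)); with the flag off, K = 1 is a single cluster with all
    worths equal.
    """
    if J < 1 or K < 1:
        raise ValueError("J and K must be positive")
    if K == 1 and k1_means_singletons:
        return make_true_worths(J, J, k1_means_singletons=False)
    if J % K != 0:
        raise ValueError(f"K={K} must divide J={J}")
    size = J // K
    assignment = np.repeat(np.arange(K), size)
    worths = 4.0 ** assignment.astype(float)
    return worths, Partition(assignment)


def generate_dataset(
    I: int,
    R: int,
    S: int,
    worths,
    rng: np.random.Generator | int | None = None,
    object_labels: Optional[Sequence[str]] = None,
) -> RankingDataset:
    """Simulate I judges, each ranking the top R of S uniformly chosen objects."""
    w = np.asarray(worths, dtype=float)
    J = len(w)
    if not 2 <= S <= J:
        raise ValueError(f"need 2 <= S <= J={J}, got S={S}")
    if not 1 <= R <= S:
        raise ValueError(f"need 1 <= R <= S={S}, got R={R}")
    if I < 1:
        raise ValueError("need at least one judge")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    observations = []
    for _ in range(I):
        considered = rng.choice(J, size=S, replace=False)
        observations.append(sample_ranking(considered, R, w, rng))
    labels = list(object_labels) if object_labels is not None else None
    return RankingDataset(J, observations, labels)


@dataclass
class ExperimentGrid:
    """Factor grid of the recovery experiment.

    Defaults span the study conditions: J = 16 objects, true cluster counts
    K in {1, 2, 4, 8} (fourfold worth separation), judge counts I in
    {100, 400, 1600}, (R, S) covering complete, partial and pairwise data,
    and Poisson rates nu in {1, K, 2K} expressed relative to the true K.
    """

    J: int = 16
    K_values: tuple[int, ...] = (1, 2, 4, 8)
    I_values: tuple[int, ...] = (100, 400, 1600)
    RS_values: tuple[tuple[int, int], ...] | None = None  # default: complete/partial/pairwise
    nu_factors: tuple[float, ...] = (1.0,)  # nu = factor * K; absolute with nu_values
    nu_values: tuple[float, ...] | None = None
    a: float = 1.0
    b: float = 1.0
    n_reps: int = 20
    n_iters: int = 10_000
    n_aug: int = 1
    k1_means_singletons: bool = True

    def rs_grid(self) -> tuple[tuple[int, int], ...]:
        if self.RS_values is not None:
            return self.RS_values
        return ((self.J, self.J), (self.J // 2, self.J), (1, 2))

    def nu_for(self, K: int) -> tuple[float, ...]:
        if self.nu_values is not None:
            return self.nu_values
        return tuple(f * K for f in self.nu_factors)


def _pair_masks(truth: Partition) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(truth.assignment)
    same = a[:, None] == a[None, :]
    off = ~np.eye(len(a), dtype=bool)
    return same & off, ~same & off


def run_experiment(
    grid: ExperimentGrid,
    seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Fit the model across the grid and measure recovery per (cell, rep).

    For every cell and replicate a fresh dataset is generated from the true
    worths and one chain is run (half burn-in). Reported per row: the mean
    absolute error of the posterior-mean normalized worths against the
    normalized truth, and the mean posterior co-clustering probability over
    truly rank-clustered and truly independent object pairs. Replicate
    seeds are spawned from the master seed by a counter-based scheme and
    recorded in the output.
    """
    from .rjmcmc import run_chain
    from .summaries import cocluster_matrix, mae, normalize_worths

    root = np.random.SeedSequence(seed)
    rows = []
    counter = 0
    for K in grid.K_values:
        truth_w, truth_g = make_true_worths(
            grid.J, K, k1_means_singletons=grid.k1_means_singletons
        )
        truth_norm = truth_w / truth_w.sum()
        clustered, independent = _pair_masks(truth_g)
        for nu in grid.nu_for(K):
            for I in grid.I_values:
                for R, S in grid.rs_grid():
                    for rep in range(grid.n_reps):
                        child = root.spawn(1)[0]
                        rng = np.random.default_rng(child)
                        data = generate_dataset(I, R, S, truth_w, rng)
                        hyper = Hyperparams(nu=nu, a=grid.a, b=grid.b)
                        chain = run_chain(
                            data, hyper, grid.n_iters, n_aug=grid.n_aug, rng=rng
                        )
                        wpost = normalize_worths(chain.retained_worths())
                        est = wpost.mean(axis=0)
                        cc = cocluster_matrix(chain)
                        row = {
                            "J": grid.J,
                            "K": K,
                            "nu": nu,
                            "I": I,
                            "R": R,
                            "S": S,
                            "rep": rep,
                            "seed_counter": counter,
                            "mae": mae(est, truth_norm),
                            "cocluster_clustered": (
                                float(cc[clustered].mean()) if clustered.any() else np.nan
                            ),
                            "cocluster_independent": (
                                float(cc[independent].mean()) if independent.any() else np.nan
                            ),
                            "k_mode": int(np.bincount(chain.retained_k()).argmax()),
                        }
                        rows.append(row)
                        counter += 1
                        if progress:
                            print(
                                f"K={K} nu={nu:g} I={I} (R,S)=({R},{S}) rep={rep}: "
                                f"mae={row['mae']:.4f}"
                            )
    return pd.DataFrame(rows)
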
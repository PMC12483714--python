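"""Posterior predictive check on pairwise win counts.

Fits the model to data it can represent (generated from BTL worths) and to
data it cannot — a cyclic tournament (rock-paper-scissors pattern), which
no single worth vector reproduces — and compares the posterior predictive
p-values.
"""

import numpy as np

from rcbtl import (
    Hyperparams,
    RankingDataset,
    RankingObservation,
    generate_dataset,
    make_true_worths,
    posterior_predictive_pvalue,
    run_chain,
)

h = Hyperparams(nu=2.0)
w, _ = make_true_worths(6, 2, k1_means_singletons=False)
rng = np.random.default_rng(0)

good = generate_dataset(100, 6, 6, w, rng)
chain = run_chain(good, h, 3000, rng=rng)
p = posterior_predictive_pvalue(chain, good, rng=rng)
print(f"model-generated data: p = {p:.2f}  (near 0.5 = adequate)")

# cyclic pairwise outcomes: A beats B, B beats C, C beats A, 60 games each
cyc = []
for winner, loser in [(0, 1), (1, 2), (2, 0)]:
    cyc += [RankingObservation([winner], [winner, loser])] * 54
    cyc += [RankingObservation([loser], [winner, loser])] * 6
cycle_data = RankingDataset(3, cyc, ["A", "B", "C"])
chain2 = run_chain(cycle_data, h, 3000, rng=rng)
p2 = posterior_predictive_pvalue(chain2, cycle_data, rng=rng)
print(f"cyclic tournament:    p = {p2:.2f}  (near 0 = misfit)")
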
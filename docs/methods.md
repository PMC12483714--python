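# Methods

## Model

Data are ordinal comparisons from I exchangeable judges over J objects.
Judge i reports an ordered prefix πᵢ of Rᵢ objects drawn from a considered
set Sᵢ ⊆ {1..J} (|Sᵢ| ≥ 2). Under the Bradley–Terry–Luce (BTL) family the
prefix is built sequentially: at stage s the judge selects one object from
the remaining considered objects with probability proportional to its
worth λⱼ > 0. A pairwise comparison is the special case |Sᵢ| = 2, Rᵢ = 1;
a complete ranking is Rᵢ = |Sᵢ| = J. When Rᵢ = |Sᵢ|, the final stage has a
single remaining object and probability 1; it is dropped from all
computations, so a ranking stored with Rᵢ = |Sᵢ| and one stored with
Rᵢ = |Sᵢ| − 1 are the same observation. Ties *within an observed ranking*
are not modeled and are rejected on input; ties in *population rank* are
the object of inference.

Worths carry a partition-based spike-and-slab fusion prior:

1. a partition g of {1..J} into K nonempty clusters, with
   P(g) ∝ f(K(g); ν), f the Poisson(ν) pmf truncated to {1..J} and
   renormalized;
2. one worth per cluster, i.i.d. Gamma(shape a, rate b);
3. each object's worth is its cluster's worth.

Because every partition with the same K receives equal mass, the induced
marginal on K is proportional to f(K)·S(J, K) (S = Stirling number of the
second kind), not f(K) itself; `prior_k_pmf` exposes the induced law and
the tests assert it. Two consequences shape the package's checks: each
λⱼ's marginal prior is exactly Gamma(a, b) regardless of ν, and the prior
probability that two given objects are tied is
Σ_K f(K)·S(J−1, K) / Σ_K f(K)·S(J, K), computable exactly for any J.

The likelihood depends on worths only through ratios; identifiability
comes from the prior, and all reporting normalizes each posterior draw to
sum to one, which makes a worth readable as the probability of being the
first choice among all J objects. Any other fixed scale would be
equivalent.

## Sampler

Each iteration performs one reversible-jump **partition step** followed by
`n_aug` **augmented Gibbs sweeps** of the cluster worths.

**Partition step.** A birth (cluster split) is attempted with probability
b_K, a death (merge of two clusters adjacent in worth order) with
d_K = 1 − b_K; b₁ = 1, b_J = 0 and b_K = ½ otherwise — the acceptance
ratio uses the actual b/d values, so any schedule is valid, and the
symmetric one maximizes dimension-changing traffic. For a birth, a
cluster with ≥ 2 members is chosen uniformly, its members are assigned to
two children independently with equal probability conditional on both
children being nonempty (2^{N−1} − 1 unordered splits), and the worth λ is
split through the mean-preserving bijection

    λ₁ = 2λu,  λ₂ = 2λ(1 − u),  u ~ Uniform(0, 1),

with inverse λ = (λ₁ + λ₂)/2, u = λ₁/(λ₁ + λ₂) and Jacobian 4λ. Deaths
pick one of the K − 1 worth-adjacent pairs uniformly and apply the
inverse. Births whose children are not adjacent in the resulting worth
order are rejected automatically — deaths can only merge adjacent pairs,
so reversibility demands it. The bijection (map, inverse, Jacobian, u
density) is one pluggable object (`SplitMergeBijection`), so an
alternative split rule is a drop-in replacement. Proposed child worths
that exactly tie an existing worth (a probability-zero event) are
rejected to keep cluster worths pairwise distinct, which is what makes
"equal expanded worth" and "same cluster" synonymous.

The acceptance ratio is the product of the likelihood ratio, the
partition-prior ratio f(K′)/f(K) (the partition-sum normalizer cancels),
the Gamma slab ratio, the proposal ratio
[d_{K+1}/K] / [b_K · (1/#eligible) · 1/(2^{N−1}−1) · q(u)] for a birth
(reciprocal for a death), and the Jacobian. Correctness is enforced by
three independent batteries in the tests: exact negation of the
reconstructed reverse move's log-ratio, recovery of the enumerated prior
when run with no data, and agreement with an exact quadrature posterior
on an enumerable instance.

**Worth step.** One latent yᵢₛ ~ Exponential(Σ_{j ∈ remaining} λⱼ) per
informative stage makes the BTL denominators cancel, leaving independent
Gamma full conditionals per cluster: shape a + (stages won by the
cluster's objects), rate b + Σ yᵢₛ · (cluster members still remaining at
that stage). Latents are drawn fresh within each sweep and never persist
across partition moves — the birth/death ratio lives on the non-augmented
posterior. `n_aug` defaults to 1; correctness holds for any n_aug ≥ 1,
and the augmentation identity is verified symbolically in the tests.

**Initialization and burn-in.** Chains start from all singletons (K = J)
with prior-drawn worths, letting clusters form during estimation instead
of being imposed; the first half of each chain is discarded by default.
Since reversible-jump samplers can be slow to traverse partition space,
the CLI runs several chains (default 4) with seeds spawned from one
master seed.

## Defaults and tunables

| parameter | meaning | default | notes |
|---|---|---|---|
| ν | Poisson rate on K | 2 | small ν encourages fusion, ν ≈ J discourages it; results should be checked across ν |
| a, b | Gamma slab shape/rate | 1, 1 | scale-irrelevant by ratio invariance; a ≤ 1 keeps density near 0 so extreme worth ratios stay reachable |
| iterations | chain length | 10,000 | with half burn-in; small-J instances mix in far fewer |
| n_aug | worth sweeps per iteration | 1 | |

## Synthetic-data generator

`make_true_worths(J, K)` builds K equal-sized rank-clusters whose worths
form the geometric sequence 4⁰, …, 4^{K−1}: one fourfold step gives the
stronger object of an adjacent pair a 0.8 pairwise win probability —
strong but not deterministic separation. The reading of K = 1 is
controlled by `k1_means_singletons` (default True: K = 1 labels the
all-singleton, no-ties regime; False: a single all-tied cluster).
`generate_dataset(I, R, S, …)` draws each judge's considered set
uniformly among size-S subsets and ranks its top R sequentially
(implemented by Gumbel perturbation of log-worths, which is
distributionally identical). `run_experiment` crosses K, ν, I and (R, S)
— defaults J = 16, K ∈ {1,2,4,8}, I ∈ {100,400,1600},
(R,S) ∈ {(J,J), (J/2,J), (1,2)}, 20 replicates — and reports, per cell
and replicate, the MAE of posterior-mean normalized worths against the
truth and the mean co-clustering probability over truly-tied and
truly-independent pairs, with replicate seeds spawned from the master
seed and recorded.

The generator emulates judges who follow the BTL process exactly, with
considered sets missing completely at random. Real data depart from this
in ways the generator does not represent — judge heterogeneity (mixtures
of preference regimes), intransitive aggregate preferences, ties or
attention effects within a ranking, informative consideration sets — so
passing recovery tests demonstrates correctness of the inference
machinery under the model, not robustness to those violations. The
posterior predictive check is the in-package tool for detecting such
misfit: its win-count discrepancy flags intransitive (cyclic) preference
structure clearly, but is insensitive by construction to misspecification
that leaves aggregate pairwise win counts unchanged (e.g., a symmetric
50/50 mixture of opposite preference camps).

## Goodness of fit

The posterior predictive p-value uses the discrepancy
D(x; λ) = Σ_{j≠j′} (n_{jj′} − e_{jj′})² / max(e_{jj′}, ε), where n_{jj′}
counts observations in which j beats j′ (ranked earlier, or ranked while
j′ is considered but unranked) and e_{jj′} is the expectation under the
fitted draw, estimated by Monte Carlo over replicates of the observed
design (same considered sets and prefix lengths; exact enumeration is
infeasible for partial designs). The sum runs over ordered pairs so both
beat directions contribute, ε = 10⁻⁸ guards empty cells, and defaults are
100 evenly spaced posterior draws with 10 expectation replicates plus one
test replicate per draw. Values near 0.5 indicate adequate fit; the form
is validated through its calibration behavior (see the fit-check tests).

## Exact small-J oracle

`rcbtl.exact` computes P(g | data) for J ≤ 7 by enumerating all
partitions and integrating the likelihood over the Gamma slab with
tensor-product Gauss–Laguerre quadrature (48 nodes per cluster dimension
after the substitution x = bλ). It shares only the flattened likelihood
terms with the sampler and is the independent reference in the
posterior-agreement tests.

## Numerical choices and edge cases

- Stage denominators in the scalar likelihood path use log-sum-exp;
  the vectorized path works on worth scales where direct sums are safe
  (posterior draws under the Gamma slab).
- Quantile summaries of K use empirical order statistics (inverse CDF),
  so credible-interval endpoints are attained integer values.
- MAP-partition ties are broken by earliest first occurrence, with a
  warning.
- An empty dataset is a legal input to the sampler (likelihood ≡ 1) and
  targets the prior — the standard correctness battery for
  reversible-jump code; the CSV readers still refuse empty files.
- Problem sizes in the validation suite are chosen to make each check
  sharp yet quick: enumerable instances use J = 3–4, prior-recovery runs
  50k iterations, and the recovery study uses J = 8 with true K = 2,
  I ∈ {100, 400, 1600} and 10k-iteration chains. The judge-count trend is
  measured on nested judge sets (each replicate draws 1600 judges once
  and fits the first 100/400/all) — common random numbers isolate the
  effect of I from dataset-to-dataset noise.

## Known limitations

- Partition moves change one cluster at a time; for large J and strongly
  multimodal clusterings, mixing across distant partitions can be slow —
  run multiple chains and compare.
- No covariates on objects or judges, no tie likelihood for observed
  ties, and a single homogeneous judge population.
- The discrete prior on partitions is exchangeable over objects; there is
  no mechanism to encode prior knowledge that specific objects are likely
  tied.
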
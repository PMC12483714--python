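"""Birth/death reversible-jump moves and the full sampler."""

import math
from collections import Counter

import numpy as np
import pytest

from rcbtl.datamodel import Hyperparams, Partition, RankingDataset, WorthState
from rcbtl.prior import prior_partition_pmf
from rcbtl.rjmcmc import (
    MEAN_PRESERVING_SPLIT,
    MoveProposal,
    acceptance_log_ratio,
    birth_prob,
    death_prob,
    initial_state,
    partition_step,
    propose_birth,
    propose_death,
    run_chain,
)


class _IndexRng:
    """Deterministic stand-in for choosing a specific proposal index."""

    def __init__(self, idx):
        self.idx = idx

    def integers(self, n):
        return self.idx


class TestBijection:
    def test_split_merge_roundtrip(self, rng):
        B = MEAN_PRESERVING_SPLIT
        for _ in range(100):
            lam, u = rng.gamma(2.0, 1.0) + 0.01, rng.uniform(0.01, 0.99)
            l1, l2 = B.split(lam, u)
            lam2, u2 = B.merge(l1, l2)
            assert lam2 == pytest.approx(lam, rel=1e-12)
            assert u2 == pytest.approx(u, rel=1e-12)
            # and the other direction
            m, v = B.merge(l1, l2)
            r1, r2 = B.split(m, v)
            assert r1 == pytest.approx(l1, rel=1e-12)
            assert r2 == pytest.approx(l2, rel=1e-12)

    def test_jacobian_matches_finite_differences(self, rng):
        B = MEAN_PRESERVING_SPLIT
        eps = 1e-6
        for _ in range(50):
            lam, u = rng.gamma(2.0, 1.0) + 0.1, rng.uniform(0.05, 0.95)
            f = lambda l, uu: np.array(B.split(l, uu))
            jac = np.column_stack(
                [
                    (f(lam + eps, u) - f(lam - eps, u)) / (2 * eps),
                    (f(lam, u + eps) - f(lam, u - eps)) / (2 * eps),
                ]
            )
            assert B.log_jacobian(lam, u) == pytest.approx(
                math.log(abs(np.linalg.det(jac))), rel=1e-6
            )


class TestMoveAvailability:
    def test_birth_unavailable_when_all_singletons(self, rng):
        st = WorthState(Partition([0, 1, 2]), [1.0, 2.0, 3.0])
        assert propose_birth(st, rng) is None

    def test_death_unavailable_at_k1(self, rng):
        st = WorthState(Partition([0, 0, 0]), [1.0])
        assert propose_death(st, rng) is None

    def test_move_probability_schedule(self):
        assert birth_prob(1, 5) == 1.0 and death_prob(1, 5) == 0.0
        assert birth_prob(5, 5) == 0.0 and death_prob(5, 5) == 1.0
        assert birth_prob(3, 5) == death_prob(3, 5) == 0.5

    def test_k1_state_partition_step_is_birth_or_nothing(self, hyper, rng):
        st = WorthState(Partition([0, 0]), [1.0])
        new, _ = partition_step(st, None, hyper, rng)
        assert new.n_clusters in (1, 2)


class TestBirth:
    def test_two_object_cluster_splits_into_singletons(self, rng):
        st = WorthState(Partition([0, 0]), [1.0])
        prop = propose_birth(st, rng)
        assert prop is not None and prop.kind == "birth"
        assert prop.new_state.partition.cluster_sizes == (1, 1)

    def test_birth_increments_k_and_preserves_membership_union(self, rng):
        st = WorthState(Partition([0, 0, 0, 1]), [1.0, 3.0])
        for _ in range(50):
            prop = propose_birth(st, rng)
            if prop is None:
                continue
            g = prop.new_state.partition
            assert g.n_clusters == 3
            assert sorted(sum(g.cluster_members, ())) == [0, 1, 2, 3]

    def test_nonadjacent_children_are_autorejected(self, rng):
        # a third cluster's worth always sits between the children iff the
        # split straddles it; every returned proposal must have adjacent kids
        st = WorthState(Partition([0, 0, 1, 2]), [1.0, 1.1, 20.0])
        for _ in range(200):
            prop = propose_birth(st, rng)
            if prop is None:
                continue
            cw = sorted(prop.new_state.cluster_worths)
            split = sorted(set(prop.new_state.cluster_worths) - set(st.cluster_worths))
            i, j = cw.index(split[0]), cw.index(split[1])
            assert abs(i - j) == 1


class TestDeath:
    def test_k2_merges_to_single_cluster(self, rng):
        st = WorthState(Partition([0, 1, 0]), [1.0, 4.0])
        prop = propose_death(st, rng)
        assert prop.new_state.partition.assignment == (0, 0, 0)
        assert prop.new_state.cluster_worths[0] == pytest.approx(2.5)

    def test_only_consecutive_worth_pairs_merge(self):
        st = WorthState(Partition([0, 1, 2]), [1.0, 2.0, 9.0])
        merged = set()
        for idx in range(2):
            prop = propose_death(st, _IndexRng(idx))
            merged.add(tuple(sorted(
                set(st.cluster_worths) - set(prop.new_state.cluster_worths)
            )))
        assert merged == {(1.0, 2.0), (2.0, 9.0)}  # never the pair (1, 9)


class TestReversibility:
    def test_reverse_death_negates_birth_terms(self, hyper, small_dataset):
        """Reconstructing the matching death after each birth must give
        exactly reciprocal proposal and Jacobian terms (and hence
        log A_birth + log A_death = 0)."""
        rng = np.random.default_rng(5)
        st = initial_state(6, hyper, rng)
        checked = 0
        for _ in range(2500):
            prop = (
                propose_birth(st, rng)
                if rng.uniform() < 0.5
                else propose_death(st, rng)
            )
            if prop is None:
                continue
            if prop.kind == "birth":
                new = prop.new_state
                for p in range(new.n_clusters - 1):
                    rev = propose_death(new, _IndexRng(p))
                    back = rev.new_state
                    if back.partition != st.partition:
                        continue
                    if not np.allclose(back.cluster_worths, st.cluster_worths, rtol=1e-9):
                        continue
                    assert rev.log_proposal_ratio + prop.log_proposal_ratio == pytest.approx(0.0, abs=1e-10)
                    assert rev.log_jacobian + prop.log_jacobian == pytest.approx(0.0, abs=1e-10)
                    la = acceptance_log_ratio(st, prop, small_dataset, hyper)
                    la_rev = acceptance_log_ratio(new, rev, small_dataset, hyper)
                    # likelihood/prior deltas evaluated at states equal to ulp
                    assert la + la_rev == pytest.approx(0.0, abs=1e-6)
                    checked += 1
                    break
                else:
                    pytest.fail("no reverse death reconstructs the pre-birth state")
            la = acceptance_log_ratio(st, prop, small_dataset, hyper)
            if math.log(rng.uniform()) < la:
                st = prop.new_state
        assert checked > 100

    def test_split_count_formula(self):
        # a 3-object cluster admits 2^{3-1} - 1 = 3 unordered nonempty splits
        members = [0, 1, 2]
        splits = set()
        for bits in range(1, 2 ** 3 - 1):
            side = frozenset(m for i, m in enumerate(members) if bits >> i & 1)
            splits.add(frozenset({side, frozenset(members) - side}))
        assert len(splits) == 3 == 2 ** (3 - 1) - 1


class TestRunChain:
    def test_deterministic_under_fixed_seed(self, hyper, small_dataset):
        c1 = run_chain(small_dataset, hyper, 300, rng=123)
        c2 = run_chain(small_dataset, hyper, 300, rng=123)
        assert np.array_equal(c1.assignments, c2.assignments)
        assert np.array_equal(c1.worths, c2.worths)

    def test_prior_recovery_on_empty_data(self, hyper):
        # with no data the invariant distribution is the PSSF prior
        J = 3
        chain = run_chain(RankingDataset(J), hyper, 20_000, rng=7)
        parts, pmf = prior_partition_pmf(J, hyper.nu)
        ret = chain.retained_assignments()
        cnt = Counter(tuple(row) for row in ret)
        emp = np.array([cnt.get(g.assignment, 0) / len(ret) for g in parts])
        assert 0.5 * np.abs(emp - pmf).sum() < 0.05

    def test_reaches_all_partitions(self, hyper):
        chain = run_chain(RankingDataset(3), hyper, 5000, rng=2)
        seen = {tuple(row) for row in chain.assignments}
        assert len(seen) == 5

    def test_ergodicity_from_opposite_initializations(self, hyper, small_dataset):
        J = small_dataset.n_objects
        rng = np.random.default_rng(9)
        from_singletons = run_chain(small_dataset, hyper, 4000, rng=rng)
        allinone = WorthState(Partition([0] * J), [1.0])
        from_fused = run_chain(small_dataset, hyper, 4000, rng=rng, init=allinone)
        k1 = np.bincount(from_singletons.retained_k(), minlength=J + 1) / 2000
        k2 = np.bincount(from_fused.retained_k(), minlength=J + 1) / 2000
        assert 0.5 * np.abs(k1 - k2).sum() < 0.1
        m1 = np.median(from_singletons.retained_worths() /
                       from_singletons.retained_worths().sum(1, keepdims=True), axis=0)
        m2 = np.median(from_fused.retained_worths() /
                       from_fused.retained_worths().sum(1, keepdims=True), axis=0)
        assert np.allclose(m1, m2, atol=0.03)

    def test_requires_data_or_init(self, hyper):
        with pytest.raises(ValueError):
            run_chain(None, hyper, 10, rng=0)

    def test_k_trace_matches_partitions(self, hyper, small_dataset):
        chain = run_chain(small_dataset, hyper, 200, rng=4)
        assert np.array_equal(chain.k_trace, chain.assignments.max(axis=1) + 1)
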
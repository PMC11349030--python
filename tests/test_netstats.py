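"""Metrics, hubs, module flows and robustness summaries, with exact oracles."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from bilingam.netstats import (
    ConfusionCounts,
    common_distinct_patterns,
    confusion_counts,
    detect_hubs,
    edge_set,
    hypergeometric_enrichment,
    jaccard,
    module_flow_counts,
    robustness_subsample,
    shd,
    tpr_fdr,
)


def graph(p, edges):
    B = np.zeros((p, p))
    for i, j in edges:
        B[i, j] = 1.0
    return B


def brute_confusion(B_true, B_est):
    """Oracle: explicit loop over all ordered pairs."""
    p = B_true.shape[0]
    tp = fp = fn = tn = 0
    for i, j in itertools.permutations(range(p), 2):
        t, e = B_true[i, j] != 0, B_est[i, j] != 0
        tp += t and e
        fp += (not t) and e
        fn += t and not e
        tn += (not t) and (not e)
    return tp, fp, fn, tn


def brute_shd(B_true, B_est):
    """Oracle: breadth-first search over graph states, one edit per move
    (insert, delete or flip a directed edge)."""
    p = B_true.shape[0]

    def key(B):
        return tuple((B != 0).astype(int).ravel())

    target = key(B_true)
    frontier = {key(B_est)}
    seen = set(frontier)
    dist = 0
    while target not in frontier:
        nxt = set()
        for state in frontier:
            A = np.array(state).reshape(p, p)
            for i, j in itertools.permutations(range(p), 2):
                for move in ("toggle", "flip"):
                    C = A.copy()
                    if move == "toggle":
                        C[i, j] = 1 - C[i, j]
                    else:
                        if not (A[i, j] and not A[j, i]):
                            continue
                        C[i, j], C[j, i] = 0, 1
                    k = key(C)
                    if k not in seen:
                        seen.add(k)
                        nxt.add(k)
        frontier = nxt
        dist += 1
        assert dist <= p * p, "oracle runaway"
    return dist


def random_dag_pair(rng, p=4):
    def one():
        order = rng.permutation(p)
        B = np.zeros((p, p))
        for a in range(p):
            for b in range(a + 1, p):
                if rng.random() < 0.4:
                    B[order[a], order[b]] = 1.0
        return B

    return one(), one()


class TestConfusionAndRates:
    def test_identical_graphs(self):
        B = graph(5, [(0, 1), (1, 2), (2, 3), (3, 4), (0, 2), (1, 3), (0, 4)])
        c = confusion_counts(B, B)
        assert (c.TP, c.FP, c.FN, c.TN) == (7, 0, 0, 13)
        assert tpr_fdr(c) == (1.0, 0.0)

    def test_flip_counts_as_fp_plus_fn(self):
        Bt = graph(3, [(0, 1), (1, 2)])
        Be = graph(3, [(0, 1), (2, 1)])
        c = confusion_counts(Bt, Be)
        assert (c.TP, c.FP, c.FN, c.TN) == (1, 1, 1, 3)
        assert tpr_fdr(c) == (0.5, 0.5)

    def test_empty_estimate_sentinels(self):
        Bt = graph(4, [(0, 1), (2, 3)])
        c = confusion_counts(Bt, np.zeros((4, 4)))
        tpr, fdr = tpr_fdr(c)
        assert (c.TP, c.FP, c.FN) == (0, 0, 2)
        assert tpr == 0.0 and fdr == 0.0

    def test_no_actual_positives_gives_nan_tpr(self):
        tpr, fdr = tpr_fdr(ConfusionCounts(0, 2, 0, 10))
        assert np.isnan(tpr) and fdr == 1.0

    def test_matches_brute_force_and_conserves_total(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            Bt, Be = random_dag_pair(rng)
            c = confusion_counts(Bt, Be)
            assert (c.TP, c.FP, c.FN, c.TN) == brute_confusion(Bt, Be)
            assert c.total == 4 * 3


class TestShd:
    def test_identical_graphs_zero(self):
        B = graph(4, [(0, 1), (1, 2)])
        assert shd(B, B) == 0

    def test_single_flip_costs_one(self):
        assert shd(graph(3, [(0, 1), (1, 2)]), graph(3, [(0, 1), (2, 1)])) == 1

    def test_empty_estimate_costs_all_insertions(self):
        B = graph(5, [(0, 1), (1, 2), (3, 4)])
        assert shd(B, np.zeros((5, 5))) == 3

    def test_matches_bfs_minimal_edit_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            Bt, Be = random_dag_pair(rng, p=4)
            assert shd(Bt, Be) == brute_shd(Bt, Be)


class TestJaccard:
    def test_equal_nonempty_sets(self):
        B = graph(3, [(0, 1), (1, 2)])
        assert jaccard(B, B) == 1.0

    def test_flip_is_a_distinct_directed_edge(self):
        assert jaccard(
            graph(3, [(0, 1), (1, 2)]), graph(3, [(0, 1), (2, 1)])
        ) == pytest.approx(1 / 3)

    def test_disjoint_sets_and_empty_convention(self):
        assert jaccard(graph(3, [(0, 1)]), graph(3, [(1, 2)])) == 0.0
        assert jaccard(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0

    def test_symmetry(self, rng):
        B1, B2 = random_dag_pair(rng, p=5)
        assert jaccard(B1, B2) == jaccard(B2, B1)


class TestHubs:
    def test_uniform_degrees_give_no_hubs(self):
        B = graph(4, [(0, 1), (1, 2), (2, 3), (3, 0)])  # every degree is 2
        rep = detect_hubs(B, mode="total")
        assert rep.hubs.size == 0

    def test_star_with_many_leaves_flags_only_center(self):
        p = 14
        B = np.zeros((p, p))
        B[0, 1:] = 1.0  # center degree 13, leaves degree 1
        rep = detect_hubs(B, mode="total")
        assert rep.total_degree[0] == 13
        assert rep.hubs.tolist() == [0]

    def test_star_center_is_out_hub_only(self):
        p = 8
        B = np.zeros((p, p))
        B[0, 1:] = 1.0
        assert detect_hubs(B, mode="out").hubs.tolist() == [0]
        assert detect_hubs(B, mode="in").hubs.size == 0

    def test_threshold_value_on_known_sequence(self):
        # explicit check of mean + 2 * population sd on [1x9, 13]
        seq = np.array([1] * 9 + [13], dtype=float)
        assert seq.mean() + 2 * seq.std() == pytest.approx(9.4)


class TestModuleFlows:
    def test_single_module_counts_all_edges(self):
        B = graph(4, [(0, 1), (1, 2), (0, 3)])
        flows, labels = module_flow_counts(B, {i: "m" for i in range(4)})
        assert flows.shape == (1, 1) and flows[0, 0] == 3

    def test_within_module_edges_stay_on_diagonal(self):
        B = graph(4, [(0, 1), (1, 0)])
        m = {0: "a", 1: "a", 2: "b", 3: "b"}
        flows, labels = module_flow_counts(B, m)
        assert labels == ["a", "b"]
        assert flows[0, 0] == 2 and flows.sum() == 2

    def test_total_conservation(self, rng):
        B1, _ = random_dag_pair(rng, p=6)
        m = {i: "ab"[i % 2] for i in range(6)}
        flows, _ = module_flow_counts(B1, m)
        assert flows.sum() == len(edge_set(B1))

    def test_unmapped_node_rejected(self):
        with pytest.raises(ValueError):
            module_flow_counts(np.zeros((3, 3)), {0: "a", 1: "a"})


def exact_tail(pop, succ, draws, obs):
    """Oracle: exact hypergeometric upper tail by rational arithmetic."""
    total = Fraction(0)
    for k in range(obs, min(succ, draws) + 1):
        total += Fraction(comb(succ, k) * comb(pop - succ, draws - k), comb(pop, draws))
    return float(total)


class TestHypergeometricEnrichment:
    def test_six_node_two_module_worked_example(self):
        # 3+3 nodes, 5 edges total, 3 observed in the A->B block of 9 pairs:
        # P[X >= 3] = 20412/142506
        m = {0: "A", 1: "A", 2: "A", 3: "B", 4: "B", 5: "B"}
        flows = np.array([[1, 3], [1, 0]])
        pv, sig, labels = hypergeometric_enrichment(flows, m, total_edges=5)
        assert pv[0, 1] == pytest.approx(20412 / 142506, abs=1e-12)
        assert pv[0, 1] == pytest.approx(0.1432, abs=5e-4)

    def test_zero_observed_is_never_significant(self):
        m = {0: "A", 1: "A", 2: "B", 3: "B"}
        flows = np.array([[2, 0], [0, 1]])
        pv, sig, _ = hypergeometric_enrichment(flows, m, total_edges=3)
        assert pv[0, 1] == pytest.approx(1.0)
        assert not sig[0, 1]

    def test_concentrated_module_has_minimal_p(self):
        m = {0: "A", 1: "A", 2: "B", 3: "B", 4: "B", 5: "B"}
        flows = np.zeros((2, 2), dtype=int)
        flows[0, 0] = 2  # both possible A-internal pairs realized
        pv, _, _ = hypergeometric_enrichment(flows, m, total_edges=2)
        assert pv[0, 0] == pv.min()

    def test_matches_exact_enumeration_on_random_configurations(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            sizes = rng.integers(2, 4, size=2)  # population <= 42 pairs
            p = int(sizes.sum())
            m = {}
            node = 0
            for lab, s in zip("AB", sizes):
                for _ in range(s):
                    m[node] = lab
                    node += 1
            pop = p * (p - 1)
            draws = int(rng.integers(1, min(10, pop)))
            # scatter draws edges over the blocks consistently
            pairs = [(i, j) for i in range(p) for j in range(p) if i != j]
            chosen = [pairs[t] for t in rng.choice(len(pairs), draws, replace=False)]
            flows = np.zeros((2, 2), dtype=int)
            lab_idx = {"A": 0, "B": 1}
            for i, j in chosen:
                flows[lab_idx[m[i]], lab_idx[m[j]]] += 1
            pv, _, _ = hypergeometric_enrichment(flows, m, total_edges=draws)
            for a in range(2):
                for b in range(2):
                    succ = sizes[a] * sizes[b] - (sizes[a] if a == b else 0)
                    expected = exact_tail(pop, int(succ), draws, int(flows[a, b]))
                    assert abs(pv[a, b] - expected) < 1e-12

    def test_inconsistent_observation_rejected(self):
        m = {0: "A", 1: "A", 2: "B"}
        flows = np.array([[5, 0], [0, 0]])  # only 2 A-internal pairs exist
        with pytest.raises(ValueError):
            hypergeometric_enrichment(flows, m, total_edges=5)


class TestPatterns:
    def test_identical_groups(self):
        B = graph(3, [(0, 1), (1, 2)])
        common, distinct = common_distinct_patterns([B, B, B])
        assert common == edge_set(B)
        assert all(not d for d in distinct)

    def test_disjoint_groups(self):
        B1 = graph(3, [(0, 1)])
        B2 = graph(3, [(1, 2)])
        common, distinct = common_distinct_patterns([B1, B2])
        assert common == set()
        assert distinct == [{(0, 1)}, {(1, 2)}]

    def test_single_shared_edge(self):
        e = (0, 1)
        B1 = graph(4, [e, (1, 2)])
        B2 = graph(4, [e, (2, 3)])
        B3 = graph(4, [e, (3, 0)])
        common, _ = common_distinct_patterns([B1, B2, B3])
        assert common == {e}


class TestRobustness:
    @staticmethod
    def correlation_estimator(threshold=0.5):
        def est(X_groups):
            out = []
            for X in X_groups:
                C = np.corrcoef(X, rowvar=False)
                np.fill_diagonal(C, 0.0)
                out.append(np.triu(np.abs(C) > threshold).astype(float))
            return out

        return est

    def test_full_fraction_deterministic_estimator_zero_sd(self, small_study):
        _, _, X_groups = small_study
        rng = np.random.default_rng(0)
        table = robustness_subsample(
            X_groups, [1.0], reps=3, estimator=self.correlation_estimator(), rng=rng
        )
        assert (table["sd_edges"] == 0.0).all()

    def test_stratified_subsample_sizes(self, small_study):
        _, _, X_groups = small_study
        calls = []

        def spy(subs):
            calls.append([s.shape[0] for s in subs])
            return [np.zeros((s.shape[1], s.shape[1])) for s in subs]

        robustness_subsample(
            X_groups, [0.5], reps=2, estimator=spy, rng=np.random.default_rng(1)
        )
        for sizes in calls:
            assert sizes == [75, 75, 75]

    def test_variance_shrinks_with_fraction(self, small_study):
        _, _, X_groups = small_study
        rng = np.random.default_rng(2)
        table = robustness_subsample(
            X_groups,
            [0.2, 0.9],
            reps=10,
            estimator=self.correlation_estimator(0.3),
            rng=rng,
        )
        sd_small = table[table.fraction == 0.2]["sd_edges"].mean()
        sd_large = table[table.fraction == 0.9]["sd_edges"].mean()
        assert sd_large <= sd_small

    def test_too_small_fraction_skipped_with_warning(self, small_study):
        _, _, X_groups = small_study
        with pytest.warns(UserWarning):
            table = robustness_subsample(
                X_groups,
                [0.01],
                reps=2,
                estimator=self.correlation_estimator(),
                rng=np.random.default_rng(3),
            )
        assert table.empty
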
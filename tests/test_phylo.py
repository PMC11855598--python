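from itertools import product

import dendropy
import numpy as np
import pandas as pd
import pytest

from clonesort import phylo


# --------------------------------------------------------------------------
# Independent oracle: minimum character changes on a topology computed by
# two-state dynamic programming (Sankoff-style), cross-validated below by
# full enumeration over internal-node state assignments.
# --------------------------------------------------------------------------

def oracle_changes_dp(tree, states: dict) -> int:
    def rec(node):
        if not isinstance(node, tuple):
            s = states[node]
            return {s: 0, 1 - s: 10 ** 6}
        lc, rc = rec(node[0]), rec(node[1])
        return {s: min(lc[t] + (s != t) for t in (0, 1))
                + min(rc[t] + (s != t) for t in (0, 1)) for s in (0, 1)}
    c = rec(tree)
    return min(c.values())


def oracle_changes_enum(tree, states: dict) -> int:
    """Exhaustive enumeration over internal-node states."""
    internals = []

    def collect(node):
        if isinstance(node, tuple):
            internals.append(node)
            collect(node[0])
            collect(node[1])
    collect(tree)

    def node_state(node, assign):
        return assign[id(node)] if isinstance(node, tuple) else states[node]

    best = None
    for combo in product((0, 1), repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        cost = 0
        stack = [tree]
        while stack:
            node = stack.pop()
            if isinstance(node, tuple):
                for child in node:
                    cost += node_state(node, assign) != node_state(child, assign)
                    stack.append(child)
        if best is None or cost < best:
            best = cost
    return best


def oracle_score(matrix: pd.DataFrame, outgroup="germline") -> int:
    pops = list(matrix.columns)
    best = None
    for sub in phylo.enumerate_topologies(pops):
        tree = (sub, outgroup)
        total = 0
        for _, row in matrix.iterrows():
            states = {p: int(row[p]) for p in pops}
            states[outgroup] = 0
            total += oracle_changes_dp(tree, states)
        if best is None or total < best:
            best = total
    return best


def _random_matrix(rng, n_pops, n_mut) -> pd.DataFrame:
    pops = [f"P{i}" for i in range(n_pops)]
    while True:
        m = rng.integers(0, 2, size=(n_mut, n_pops))
        if (m.sum(axis=1) > 0).all():
            return pd.DataFrame(m, columns=pops)


class TestOracleSelfConsistency:
    def test_dp_equals_enumeration(self):
        rng = np.random.default_rng(44)
        for _ in range(30):
            n_pops = int(rng.integers(2, 5))
            matrix = _random_matrix(rng, n_pops, int(rng.integers(1, 8)))
            pops = list(matrix.columns)
            for sub in phylo.enumerate_topologies(pops)[:10]:
                tree = (sub, "germline")
                for _, row in matrix.iterrows():
                    states = {p: int(row[p]) for p in pops}
                    states["germline"] = 0
                    assert (oracle_changes_dp(tree, states)
                            == oracle_changes_enum(tree, states))


class TestTopologyEnumeration:
    @pytest.mark.parametrize("n,count", [(2, 1), (3, 3), (4, 15), (5, 105)])
    def test_double_factorial_counts(self, n, count):
        trees = phylo.enumerate_topologies([f"L{i}" for i in range(n)])
        assert len(trees) == count
        # all distinct as canonical structures
        canon = {str(phylo._canonical(t)) for t in trees}
        assert len(canon) == count


class TestMaxParsimony:
    def test_all_shared_mutations_land_on_trunk(self):
        matrix = pd.DataFrame(1, index=range(25), columns=["A", "B", "C"])
        res = phylo.max_parsimony_tree(matrix)
        assert res.score == 25
        assert res.branch_counts[frozenset({"A", "B", "C"})] == 25
        assert sum(res.branch_counts.values()) == res.score

    def test_two_population_score(self):
        matrix = pd.DataFrame({"A": [1, 1, 0], "B": [1, 0, 1]})
        res = phylo.max_parsimony_tree(matrix)
        # one gain per mutation present in >= 1 population
        assert res.score == 3

    def test_patient_like_blocks_group_lineages(self):
        rows = ([{"PST1": 1, "PST2": 1, "MT1": 1, "MT2": 1}] * 20
                + [{"PST1": 1, "PST2": 1, "MT1": 1, "MT2": 0}] * 10
                + [{"PST1": 0, "PST2": 1, "MT1": 1, "MT2": 0}] * 6
                + [{"PST1": 1, "PST2": 0, "MT1": 0, "MT2": 1}] * 8)
        matrix = pd.DataFrame(rows)
        res = phylo.max_parsimony_tree(matrix)
        assert res.score == oracle_score(matrix)
        # MT1 pairs with PST2, and the MT2 lineage diverges before the
        # (PST1, PST2, MT1) clade forms — the early-divergence topology
        assert frozenset({"PST2", "MT1"}) in res.branch_counts
        assert frozenset({"PST1", "PST2", "MT1"}) in res.branch_counts
        assert res.branch_counts[frozenset({"PST2", "MT1"})] >= 6

    def test_score_matches_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n_pops = int(rng.integers(2, 6))
            n_mut = int(rng.integers(1, 13))
            matrix = _random_matrix(rng, n_pops, n_mut)
            res = phylo.max_parsimony_tree(matrix)
            assert res.score == oracle_score(matrix)
            assert sum(res.branch_counts.values()) == res.score

    def test_invariance_to_column_and_row_permutation(self):
        rng = np.random.default_rng(8)
        matrix = _random_matrix(rng, 4, 10)
        res = phylo.max_parsimony_tree(matrix)
        shuffled = matrix.sample(frac=1, random_state=1)[["P2", "P0", "P3", "P1"]]
        assert phylo.max_parsimony_tree(shuffled).score == res.score

    def test_score_bounds(self):
        rng = np.random.default_rng(9)
        matrix = _random_matrix(rng, 4, 12)
        res = phylo.max_parsimony_tree(matrix)
        n_patterns = len(np.unique(matrix.to_numpy(), axis=0))
        assert n_patterns <= res.score <= int(matrix.to_numpy().sum())

    def test_newick_parses_and_contains_outgroup(self):
        matrix = pd.DataFrame({"A": [1, 1], "B": [1, 0], "C": [1, 0]})
        res = phylo.max_parsimony_tree(matrix)
        tree = dendropy.Tree.get(data=res.newick, schema="newick")
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert labels == {"A", "B", "C", "germline"}

    def test_too_many_populations_raise(self):
        matrix = pd.DataFrame(1, index=range(2), columns=[f"P{i}" for i in range(11)])
        with pytest.raises(ValueError, match="exhaustive"):
            phylo.max_parsimony_tree(matrix)

    def test_all_zero_row_rejected(self):
        matrix = pd.DataFrame({"A": [1, 0], "B": [1, 0]})
        with pytest.raises(ValueError):
            phylo.max_parsimony_tree(matrix)


class TestTrunkClassification:
    def test_present_in_all_is_trunk_in_both_modes(self):
        matrix = pd.DataFrame({"A": [1], "B": [1], "C": [1], "D": [1]})
        assert phylo.classify_trunk(matrix, "strict").iloc[0] == "trunk"
        assert phylo.classify_trunk(matrix, "biopsy").iloc[0] == "trunk"

    def test_single_population_is_private_in_both_modes(self):
        matrix = pd.DataFrame({"A": [1], "B": [0], "C": [0], "D": [0]})
        assert phylo.classify_trunk(matrix, "strict").iloc[0] == "private"
        assert phylo.classify_trunk(matrix, "biopsy").iloc[0] == "private"

    def test_partial_sharing_differs_by_mode(self):
        matrix = pd.DataFrame({"A": [1], "B": [1], "C": [0], "D": [0]})
        assert phylo.classify_trunk(matrix, "strict").iloc[0] == "shared"
        assert phylo.classify_trunk(matrix, "biopsy").iloc[0] == "trunk"

    def test_unknown_mode_raises(self):
        matrix = pd.DataFrame({"A": [1], "B": [1]})
        with pytest.raises(ValueError):
            phylo.classify_trunk(matrix, "nope")
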
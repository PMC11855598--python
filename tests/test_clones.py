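import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import beta as beta_dist
from sklearn.metrics import adjusted_rand_score

from clonesort import clones
from clonesort.clones import (CCFMixtureModel, MutationCluster, build_clone_tree,
                              ccf_trace, filter_clusters, infer_seeding)
from conftest import truth_labels_for


def _simple_model(ccf_rows, depth=150, purity=0.9, seed=0):
    """Model over synthetic reads drawn at the given per-mutation CCF rows."""
    rng = np.random.default_rng(seed)
    C = np.asarray(ccf_rows, dtype=float)
    n, P = C.shape
    a = np.full((n, P), purity / (purity * 2 + (1 - purity) * 2))
    d = np.full((n, P), float(depth))
    alt = rng.binomial(depth, a * C)
    return CCFMixtureModel(alt, d, a, [f"p{j}" for j in range(P)])


def _mk_cluster(cid, size, ccf: dict):
    pops = list(ccf)
    return MutationCluster(
        cluster_id=cid, member_ids=list(range(size)), member_rows=np.arange(size),
        size=size, ccf=ccf,
        ci_low={p: max(v - 0.05, 0.0) for p, v in ccf.items()},
        ci_high={p: min(v + 0.05, 1.0) for p, v in ccf.items()},
        clonality={p: "clonal" if v >= 0.9 else "subclonal" for p, v in ccf.items()},
    )


class TestMixtureFit:
    def test_all_truncal_gives_single_cluster(self):
        model = _simple_model([[1.0, 1.0]] * 120, seed=1)
        res = model.fit(k_max=4, n_init=5, seed=1)
        assert res.n_clusters == 1
        assert np.allclose(res.cluster_ccfs, 1.0, atol=0.05)

    def test_two_separated_clusters_selected_by_bic(self):
        rows = [[1.0, 1.0]] * 200 + [[0.3, 1.0]] * 200
        model = _simple_model(rows, seed=2)
        res = model.fit(k_max=4, n_init=10, seed=2)
        assert res.n_clusters == 2

        # independent oracle: brute-force BIC for K=1 vs K=2 with centers
        # found by direct grid maximisation of the binomial likelihood
        def loglik(centers, weights):
            a, d, alt = model.conversion, model.depth, model.alt
            parts = []
            for c, w in zip(centers, weights):
                f = np.clip(a * np.asarray(c), 1e-12, 1 - 1e-12)
                ll = (alt * np.log(f) + (d - alt) * np.log1p(-f)).sum(axis=1)
                parts.append(np.log(w) + ll)
            const = (gammaln(d + 1) - gammaln(alt + 1) - gammaln(d - alt + 1)).sum()
            return np.logaddexp.reduce(np.array(parts), axis=0).sum() + const

        grid = np.linspace(0.01, 1.0, 100)
        best1 = max(loglik([[g1, g2]], [1.0]) for g1 in grid[::5] for g2 in grid[::5])
        n = model.alt.shape[0]
        bic1 = -2 * best1 + 2 * np.log(n)
        ll2 = loglik([[1.0, 1.0], [0.3, 1.0]], [0.5, 0.5])
        bic2 = -2 * ll2 + 5 * np.log(n)
        assert bic2 < bic1
        assert res.bic_by_k[2] < res.bic_by_k[1]

    def test_loglik_monotone_over_iterations(self):
        rows = [[1.0, 1.0]] * 100 + [[0.4, 0.2]] * 100 + [[0.1, 0.7]] * 60
        model = _simple_model(rows, seed=3)
        res = model.fit(k_max=4, n_init=5, seed=3)
        trace = np.array(res.loglik_trace)
        assert (np.diff(trace) >= -1e-6).all()

    def test_deterministic_under_fixed_seed(self):
        rows = [[1.0, 1.0]] * 80 + [[0.4, 0.1]] * 80
        m1 = _simple_model(rows, seed=4)
        r1 = m1.fit(k_max=3, n_init=5, seed=9)
        r2 = _simple_model(rows, seed=4).fit(k_max=3, n_init=5, seed=9)
        assert np.array_equal(r1.labels, r2.labels)
        assert np.allclose(r1.cluster_ccfs, r2.cluster_ccfs)
        assert r1.loglik == r2.loglik

    def test_patient_like_recovery_ari(self, patient1_fit):
        cfg, res_sim, retained, results = patient1_fit
        truth = truth_labels_for(res_sim, retained)
        assert adjusted_rand_score(truth, results.labels) >= 0.9

    def test_input_validation(self):
        with pytest.raises(ValueError):
            CCFMixtureModel(np.ones((3, 2)), np.ones((3, 3)), np.ones((3, 2)), ["a", "b"])
        model = _simple_model([[1.0, 1.0]] * 10)
        with pytest.raises(ValueError):
            model.fit(k_max=0)

    def test_summary_has_one_row_per_cluster(self, patient1_fit):
        *_, results = patient1_fit
        summary = results.summary()
        assert len(summary) == len(results.clusters())
        assert {"cluster", "size", "weight"} <= set(summary.columns)


class TestFilterClusters:
    def test_small_cluster_discarded(self):
        cs = [_mk_cluster(0, 298, {"A": 1.0}), _mk_cluster(1, 199, {"A": 0.5}),
              _mk_cluster(2, 4, {"A": 0.2})]
        kept, unassigned = filter_clusters(cs)
        assert [c.cluster_id for c in kept] == [0, 1]
        assert len(unassigned) == 4

    def test_boundary_size_five_kept(self):
        kept, unassigned = filter_clusters([_mk_cluster(0, 5, {"A": 1.0})])
        assert len(kept) == 1 and not unassigned

    def test_empty_input(self):
        assert filter_clusters([]) == ([], [])

    def test_mutation_conservation(self):
        cs = [_mk_cluster(i, s, {"A": 1.0}) for i, s in enumerate((12, 3, 7, 2))]
        kept, unassigned = filter_clusters(cs)
        assert sum(c.size for c in kept) + len(unassigned) == 24


class TestCloneTree:
    def test_root_child_edge(self):
        cs = [_mk_cluster(0, 50, {"A": 1.0, "B": 1.0}),
              _mk_cluster(1, 20, {"A": 0.4, "B": 0.0})]
        tree = build_clone_tree(cs)
        assert tree.root == 0 and tree.edges == [(0, 1)]

    def test_chain_requires_containment_in_all_populations(self):
        root = _mk_cluster(0, 50, {"A": 1.0, "B": 1.0})
        # B-population CCFs forbid nesting: both children attach to the root
        c1 = _mk_cluster(1, 20, {"A": 0.6, "B": 0.2})
        c2 = _mk_cluster(2, 20, {"A": 0.5, "B": 0.4})
        tree = build_clone_tree([root, c1, c2])
        assert sorted(tree.edges) == [(0, 1), (0, 2)]

    def test_chain_formed_when_containment_holds(self):
        root = _mk_cluster(0, 50, {"A": 1.0, "B": 1.0})
        c1 = _mk_cluster(1, 20, {"A": 0.6, "B": 0.5})
        c2 = _mk_cluster(2, 20, {"A": 0.5, "B": 0.4})
        tree = build_clone_tree([root, c1, c2])
        assert sorted(tree.edges) == [(0, 1), (1, 2)]

    def test_no_truncal_cluster_raises(self):
        cs = [_mk_cluster(0, 50, {"A": 1.0, "B": 0.3})]
        with pytest.raises(ValueError, match="truncal"):
            build_clone_tree(cs)

    def test_patient_like_tree_matches_truth(self, patient1_fit):
        cfg, res_sim, retained, results = patient1_fit
        clusters, _ = filter_clusters(results.clusters())
        tree = build_clone_tree(clusters)
        # map fitted clusters to truth clusters by majority truth label
        truth = np.array(truth_labels_for(res_sim, retained))
        to_truth = {}
        for c in clusters:
            labels = truth[c.member_rows]
            to_truth[c.cluster_id] = np.bincount(labels).argmax()
        recovered = {(to_truth[p], to_truth[c]) for p, c in tree.edges}
        expected = {(p, c) for c, p in res_sim.truth.tree.items() if p is not None}
        assert recovered == expected

    def test_every_edge_satisfies_containment(self, patient1_fit):
        *_, results = patient1_fit
        clusters, _ = filter_clusters(results.clusters())
        tree = build_clone_tree(clusters, tol=0.05)
        nodes = {c.cluster_id: c for c in clusters}
        for parent, child in tree.edges:
            if child in tree.orphans:
                continue
            for p in tree.populations:
                assert nodes[child].ccf[p] <= nodes[parent].ccf[p] + 0.05

    def test_newick_and_dict_outputs(self):
        cs = [_mk_cluster(0, 50, {"A": 1.0}), _mk_cluster(1, 20, {"A": 0.4})]
        tree = build_clone_tree(cs)
        assert tree.to_newick() == "(C1:20)C0:50;"
        d = tree.to_dict()
        assert d["root"] == 0 and d["edges"] == [[0, 1]]


class TestSeeding:
    def test_exclusive_clusters_decide(self):
        pops = {"PST1": "primary", "PST2": "primary", "MT1": "metastasis",
                "MT2": "metastasis"}
        cs = [
            _mk_cluster(0, 100, {"PST1": 1, "PST2": 1, "MT1": 1, "MT2": 1}),
            _mk_cluster(1, 30, {"PST1": 0, "PST2": 1, "MT1": 1, "MT2": 0}),
            _mk_cluster(3, 40, {"PST1": 1, "PST2": 0, "MT1": 0, "MT2": 1}),
            _mk_cluster(4, 10, {"PST1": 0.4, "PST2": 0, "MT1": 0, "MT2": 0.5}),
        ]
        s = infer_seeding(cs, pops)
        assert s.assignments == {"MT1": "PST2", "MT2": "PST1"}
        assert not s.unresolved

    def test_cnv_correlation_breaks_ties(self):
        import pandas as pd
        pops = {"PST1": "primary", "PST2": "primary", "MT1": "metastasis"}
        cs = [_mk_cluster(0, 100, {"PST1": 1, "PST2": 1, "MT1": 1})]
        corr = pd.DataFrame(
            [[1.0, 0.5, 0.66], [0.5, 1.0, 0.99], [0.66, 0.99, 1.0]],
            index=["PST1", "PST2", "MT1"], columns=["PST1", "PST2", "MT1"])
        s = infer_seeding(cs, pops, cnv_correlation=corr)
        assert s.assignments["MT1"] == "PST2"
        assert s.evidence["MT1"]["used_cnv_tiebreak"]

    def test_single_primary_takes_all(self):
        pops = {"PST": "primary", "MT1": "metastasis", "MT2": "metastasis"}
        cs = [_mk_cluster(0, 10, {"PST": 1, "MT1": 1, "MT2": 1})]
        s = infer_seeding(cs, pops)
        assert s.assignments == {"MT1": "PST", "MT2": "PST"}

    def test_unresolved_without_evidence(self):
        pops = {"P1": "primary", "P2": "primary", "M": "metastasis"}
        cs = [_mk_cluster(0, 10, {"P1": 1, "P2": 1, "M": 1})]
        s = infer_seeding(cs, pops)
        assert s.assignments["M"] is None and s.unresolved == ["M"]

    def test_no_primary_raises(self):
        with pytest.raises(ValueError):
            infer_seeding([], {"M": "metastasis"})


class TestCcfTrace:
    def test_truncal_cluster_flat_at_one(self):
        c = _mk_cluster(0, 50, {"A": 1.0, "B": 1.0})
        trace = ccf_trace([c], ["A", "B"])
        assert (trace["ccf"] == 1.0).all()

    def test_absent_population_touches_zero(self, patient1_fit):
        *_, results = patient1_fit
        clusters, _ = filter_clusters(results.clusters())
        trace = ccf_trace(clusters, results.populations)
        absent = trace[trace["ccf"] < 0.02]
        assert len(absent) > 0
        assert (absent["ci_low"] <= 0.01).all()

    def test_pooled_band_coverage(self):
        # 500 replicate 20-mutation clusters at CCF 0.5: the pooled 95% band
        # should cover the truth in >= 93% of replicates
        rng = np.random.default_rng(31)
        a, depth, n_mut = 0.45, 150, 20
        hits = 0
        for _ in range(500):
            alts = rng.binomial(depth, a * 0.5, size=n_mut)
            lo, hi, _ = clones._pooled_band(alts.sum(), depth * n_mut, a)
            hits += int(lo <= 0.5 <= hi)
        assert hits / 500 >= 0.93
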
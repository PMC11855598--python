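"""Repeated-simulation recovery studies over the full estimator chain.

These drive the generative model end to end — simulate, filter, cluster,
build the tree, infer seeding — and score the results against the simulator's
ground truth. They are the package's internal-consistency checks; see the
methods note for what they do and do not certify about real data.
"""

from __future__ import annotations

import numpy as np

from . import cnv as cnv_mod
from .ccf import forward_vaf, ccf_interval
from .clones import CCFMixtureModel, build_clone_tree, filter_clusters, infer_seeding
from .sim import cn_lookup_from_profiles, patient1_config, simulate_patient
from .variants import apply_filters


def _adjusted_rand(a, b) -> float:
    """Adjusted Rand index between two label vectors (pair-counting form)."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) // 2

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def recover_one_patient(seed: int, scale: float = 0.25, depth_mean: float = 150.0,
                        k_max: int = 8, n_init: int = 20) -> dict:
    """Simulate one polygenomic patient and score cluster + seeding recovery."""
    cfg = patient1_config(seed=seed, scale=scale, depth_mean=depth_mean)
    res = simulate_patient(cfg)
    retained, _ = apply_filters(res.variants)
    pops = cfg.population_names()
    purity = {p.name: p.purity_postsort for p in cfg.populations}
    lookup = cn_lookup_from_profiles(res.cn_profiles)
    model = CCFMixtureModel.from_variants(retained, pops, purity, lookup)
    results = model.fit(k_max=k_max, n_init=n_init, seed=seed)

    lut = {tuple(k): int(v) for k, v in zip(res.variants.index, res.truth.assignments)}
    truth_labels = [lut[tuple(i)] for i in retained.index]
    ari = _adjusted_rand(truth_labels, results.labels)

    clusters, _ = filter_clusters(results.clusters())
    tree = build_clone_tree(clusters)
    profiles = [cnv_mod.CNSegmentProfile(p, res.cn_profiles[p], res.truth.ploidy[p])
                for p in pops]
    corr, _ = cnv_mod.correlation_matrix(profiles)
    sites = {p.name: p.site for p in cfg.populations}
    seeding = infer_seeding(clusters, sites, cnv_correlation=corr)
    return {
        "seed": seed,
        "n_mutations": len(retained),
        "ari": ari,
        "k_selected": results.n_clusters,
        "seeding_correct": seeding.assignments == res.truth.seeding,
        "tree_violations": len(tree.violations),
    }


def seeding_recovery_study(seeds=range(1, 21), scale: float = 0.25,
                           depth_mean: float = 150.0) -> dict:
    """Cluster/seeding recovery across replicate polygenomic patients."""
    runs = [recover_one_patient(s, scale=scale, depth_mean=depth_mean) for s in seeds]
    aris = [r["ari"] for r in runs]
    return {
        "n_patients": len(runs),
        "seeding_correct": sum(r["seeding_correct"] for r in runs),
        "ari_min": float(min(aris)),
        "ari_median": float(np.median(aris)),
        "runs": runs,
    }


def interval_coverage_study(n_sites: int = 2000, ccf_true: float = 0.6,
                            purity: float = 0.9, depth: int = 150,
                            seed: int = 0) -> float:
    """Empirical coverage of the 95% CCF interval at a fixed true CCF."""
    rng = np.random.default_rng(seed)
    vaf = forward_vaf(ccf_true, purity, 2, 2, 1)
    alts = rng.binomial(depth, vaf, size=n_sites)
    lo, hi = ccf_interval(alts, np.full(n_sites, depth), purity, 2, 2, 1)
    return float(np.mean((lo <= ccf_true) & (ccf_true <= hi)))
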
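"""Multi-sample CCF clustering, clone trees, and metastasis-seeding inference.

The clustering model
--------------------
Every somatic mutation i is observed in every sorted population p of a
patient as an (alt_ip, depth_ip) read-count pair. A mutation belonging to
cluster k with per-population cancer cell fractions c_kp generates

    alt_ip ~ Binomial(depth_ip, a_ip * c_kp)

where a_ip = purity_p * m_ip / (purity_p * CN_t,ip + (1 - purity_p) * 2) is
the deterministic CCF -> VAF conversion at that locus (multiplicity m and
local copy number from the CCF step). The finite mixture over K clusters is
fitted by EM with a k-means++-style seeded initialisation on naive CCF
vectors, multiple restarts, and exact per-coordinate M-steps (the expected
complete-data log-likelihood is concave in each c_kp, maximised by a
safeguarded Newton iteration, so the observed log-likelihood is
non-decreasing). K is selected by BIC over 1..K_max. This is a deterministic,
desk-scale replacement for Dirichlet-process subclonal-reconstruction
samplers.

Downstream, clusters below 5 mutations are discarded, the remaining clusters
are arranged into a rooted clone tree by CCF containment (a child's CCF
cannot exceed its parent's in any population), and each metastatic population
is assigned to the primary-site population it most plausibly seeded from:
the primary sharing the most clusters exclusively with that metastasis, with
copy-number-profile correlation as the tie-breaker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import beta as beta_dist

from . import ccf as ccf_mod

_EPS = 1e-9
_F_MAX = 1.0 - 1e-9


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class CCFMixtureModel:
    """Finite binomial-mixture model of per-population mutation CCFs.

    Parameters
    ----------
    alt, depth : (n, P) integer arrays of alt-supporting reads and depths.
    conversion : (n, P) array of a_ip factors mapping CCF to expected VAF.
    populations : population ids (length P).
    mutation_ids : optional per-row identifiers (defaults to 0..n-1).
    """

    def __init__(self, alt, depth, conversion, populations, mutation_ids=None):
        self.alt = np.asarray(alt, dtype=float)
        self.depth = np.asarray(depth, dtype=float)
        self.conversion = np.asarray(conversion, dtype=float)
        if not (self.alt.shape == self.depth.shape == self.conversion.shape):
            raise ValueError("alt, depth and conversion must share one (n, P) shape")
        if (self.alt > self.depth).any():
            raise ValueError("alt reads cannot exceed depth")
        self.populations = list(populations)
        if len(self.populations) != self.alt.shape[1]:
            raise ValueError("populations length must match data columns")
        n = self.alt.shape[0]
        self.mutation_ids = list(mutation_ids) if mutation_ids is not None else list(range(n))
        # binomial coefficient terms: constant in c, kept so reported
        # log-likelihoods are true log-probabilities
        self._log_binom = (gammaln(self.depth + 1) - gammaln(self.alt + 1)
                           - gammaln(self.depth - self.alt + 1)).sum()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_variants(cls, variants: pd.DataFrame, populations, purity: dict,
                      cn_lookup=None) -> "CCFMixtureModel":
        """Build from a wide variant table: multiplicities and conversion
        factors are derived per (mutation, population) via the CCF step."""
        n = len(variants)
        P = len(populations)
        alt = np.zeros((n, P))
        depth = np.zeros((n, P))
        conv = np.zeros((n, P))
        for j, pop in enumerate(populations):
            a = variants[f"alt_{pop}"].to_numpy(float)
            d = np.maximum(variants[f"dp_{pop}"].to_numpy(float), 1.0)
            if cn_lookup is None:
                cn_t = np.full(n, 2.0)
            else:
                cn_t = np.array([float(cn_lookup(pop, c, p)[0])
                                 for c, p in zip(variants["chrom"], variants["pos"])])
            p_pop = purity[pop]
            vaf = a / d
            m = ccf_mod.estimate_multiplicity(vaf, p_pop, cn_t)
            alt[:, j] = a
            depth[:, j] = d
            conv[:, j] = p_pop * m / (p_pop * cn_t + (1 - p_pop) * 2.0)
        return cls(alt, depth, conv, populations, mutation_ids=list(variants.index))

    # -- EM internals ------------------------------------------------------

    def _per_site_loglik(self, centers: np.ndarray) -> np.ndarray:
        """(K, n, P) binomial log-likelihood terms (no coefficient constants)."""
        f = self.conversion[None, :, :] * centers[:, None, :]
        np.clip(f, _EPS, _F_MAX, out=f)
        return self.alt * np.log(f) + (self.depth - self.alt) * np.log1p(-f)

    def _loglik_matrix(self, centers: np.ndarray) -> np.ndarray:
        """(n, K) per-mutation log-likelihood under each cluster (no mixing
        weights, no binomial-coefficient constants)."""
        return self._per_site_loglik(centers).sum(axis=2).T

    def _q_per_coordinate(self, resp: np.ndarray, centers: np.ndarray) -> np.ndarray:
        """(K, P) expected complete-data log-likelihood, separable by (k, p)."""
        return np.einsum("nk,knp->kp", resp, self._per_site_loglik(centers))

    def _m_step_centers(self, resp: np.ndarray, centers: np.ndarray) -> np.ndarray:
        """Per-(k,p) Newton maximisation of the concave Q; never decreases Q.

        The expected complete-data log-likelihood is strictly concave in each
        c_kp, so a clipped Newton iteration converges; a final elementwise
        comparison against the incoming centers guarantees monotonicity of
        the EM even when Newton is stopped early.
        """
        a = self.conversion          # (n, P)
        active = a > 0
        alt = np.where(active, self.alt, 0.0)
        refn = self.depth - self.alt
        c = np.clip(centers, 1e-4, 1.0)
        for _ in range(15):
            f = a[None, :, :] * c[:, None, :]
            np.clip(f, None, _F_MAX, out=f)
            w = a / (1 - f)          # (K, n, P)
            grad = np.einsum("nk,knp->kp", resp, np.where(active, -refn[None] * w, 0.0)) \
                + np.einsum("nk,np->kp", resp, alt) / np.maximum(c, _EPS)
            hess = -np.einsum("nk,knp->kp", resp, np.where(active, refn[None] * w * w, 0.0)) \
                - np.einsum("nk,np->kp", resp, alt) / np.maximum(c, _EPS) ** 2
            step = np.where(hess < 0, grad / hess, 0.0)
            c_next = np.clip(c - step, 1e-6, 1.0)
            if np.abs(c_next - c).max() < 1e-7:
                c = c_next
                break
            c = c_next
        # safeguard: keep whichever coordinate value has the higher Q
        q_old = self._q_per_coordinate(resp, centers)
        q_new = self._q_per_coordinate(resp, c)
        return np.where(q_new >= q_old, c, centers)

    def _naive_ccf(self) -> np.ndarray:
        vaf = np.divide(self.alt, self.depth,
                        out=np.zeros_like(self.alt), where=self.depth > 0)
        x = np.divide(vaf, self.conversion,
                      out=np.zeros_like(vaf), where=self.conversion > 0)
        return np.clip(x, 0.0, 1.0)

    def _init_centers(self, X: np.ndarray, k: int, rng) -> np.ndarray:
        """k-means++-style seeding on the naive CCF vectors."""
        n = X.shape[0]
        centers = [X[rng.integers(n)]]
        for _ in range(1, k):
            d2 = np.min([((X - c) ** 2).sum(axis=1) for c in centers], axis=0)
            total = d2.sum()
            if total <= 0:
                centers.append(X[rng.integers(n)])
            else:
                centers.append(X[rng.choice(n, p=d2 / total)])
        return np.clip(np.array(centers), 0.01, 1.0)

    def _run_em(self, k: int, rng, max_iter: int, tol: float):
        n = self.alt.shape[0]
        X = self._naive_ccf()
        centers = self._init_centers(X, k, rng)
        log_w = np.full(k, -np.log(k))
        prev = -np.inf
        trace = []
        for _ in range(max_iter):
            ll = self._loglik_matrix(centers) + log_w
            norm = logsumexp(ll, axis=1)
            loglik = norm.sum() + self._log_binom
            trace.append(loglik)
            resp = np.exp(ll - norm[:, None])
            centers = self._m_step_centers(resp, centers)
            w = resp.mean(axis=0)
            log_w = np.log(np.maximum(w, _EPS / n))
            if loglik - prev < tol and np.isfinite(prev):
                break
            prev = loglik
        ll = self._loglik_matrix(centers) + log_w
        norm = logsumexp(ll, axis=1)
        loglik = norm.sum() + self._log_binom
        trace.append(loglik)
        resp = np.exp(ll - norm[:, None])
        return loglik, centers, np.exp(log_w), resp, trace

    # -- public fitting API ------------------------------------------------

    def fit(self, k_max: int = 8, n_init: int = 20, seed: int = 0,
            max_iter: int = 150, tol: float = 1e-3) -> "CCFMixtureResults":
        """Fit mixtures for K = 1..k_max and select K by BIC.

        Deterministic for a fixed seed: restarts draw their initialisations
        from one seeded generator and the best-likelihood restart wins.
        """
        if k_max < 1:
            raise ValueError("k_max must be >= 1")
        n, P = self.alt.shape
        if n < 1:
            raise ValueError("need at least one mutation")
        rng = np.random.default_rng(seed)
        bic_by_k, best = {}, None
        for k in range(1, min(k_max, n) + 1):
            k_best = None
            for _ in range(n_init if k > 1 else 1):
                out = self._run_em(k, rng, max_iter, tol)
                if k_best is None or out[0] > k_best[0]:
                    k_best = out
            loglik, centers, weights, resp, trace = k_best
            n_params = k * P + (k - 1)
            bic = -2.0 * loglik + n_params * np.log(n)
            bic_by_k[k] = bic
            if best is None or bic < best[0]:
                best = (bic, k, loglik, centers, weights, resp, trace)
        bic, k, loglik, centers, weights, resp, trace = best
        return CCFMixtureResults(
            model=self, n_clusters=k, cluster_ccfs=centers, weights=weights,
            responsibilities=resp, labels=resp.argmax(axis=1),
            loglik=loglik, bic=bic, bic_by_k=bic_by_k, seed=seed,
            loglik_trace=trace,
        )


@dataclass
class CCFMixtureResults:
    """Fitted CCF mixture: cluster centres, assignments, and diagnostics."""

    model: CCFMixtureModel
    n_clusters: int
    cluster_ccfs: np.ndarray          # (K, P)
    weights: np.ndarray
    responsibilities: np.ndarray
    labels: np.ndarray                # per-mutation hard assignment
    loglik: float
    bic: float
    bic_by_k: dict
    seed: int
    loglik_trace: list = field(default_factory=list)  # best run, per EM iteration

    @property
    def populations(self) -> list:
        return self.model.populations

    def clusters(self) -> list["MutationCluster"]:
        """Materialise per-cluster summaries with pooled 95% CCF bands."""
        out = []
        for k in range(self.n_clusters):
            members = np.flatnonzero(self.labels == k)
            if members.size == 0:
                continue
            out.append(_make_cluster(self, k, members))
        return out

    def summary(self) -> pd.DataFrame:
        """One row per non-empty cluster: size, weight, per-population CCF."""
        rows = []
        for cl in self.clusters():
            row = {"cluster": cl.cluster_id, "size": cl.size,
                   "weight": float(self.weights[cl.cluster_id])}
            for p in self.populations:
                row[f"ccf_{p}"] = round(cl.ccf[p], 3)
            rows.append(row)
        df = pd.DataFrame(rows)
        df.attrs["loglik"] = self.loglik
        df.attrs["bic"] = self.bic
        return df


@dataclass
class MutationCluster:
    cluster_id: int
    member_ids: list
    member_rows: np.ndarray
    size: int
    ccf: dict                   # population -> mean CCF
    ci_low: dict
    ci_high: dict
    clonality: dict             # population -> "clonal" | "subclonal"


def _pooled_band(alt_sum, depth_sum, a_mean, level=0.95):
    lo_v = beta_dist.ppf((1 - level) / 2, alt_sum + 0.5, depth_sum - alt_sum + 0.5)
    hi_v = beta_dist.ppf(1 - (1 - level) / 2, alt_sum + 0.5, depth_sum - alt_sum + 0.5)
    if alt_sum == 0:
        lo_v = 0.0
    if a_mean <= 0:
        return 0.0, 0.0, 1.0 if alt_sum == 0 else 0.0
    lo = min(lo_v / a_mean, 1.0)
    hi = min(hi_v / a_mean, 1.0)
    p_sub = beta_dist.cdf(min(0.9 * a_mean, 1.0), alt_sum + 0.5, depth_sum - alt_sum + 0.5)
    return lo, hi, 1.0 - p_sub


def _make_cluster(res: CCFMixtureResults, k: int, members: np.ndarray) -> MutationCluster:
    m = res.model
    ccf, lo_d, hi_d, clon = {}, {}, {}, {}
    for j, pop in enumerate(m.populations):
        alt_sum = float(m.alt[members, j].sum())
        depth_sum = float(m.depth[members, j].sum())
        w = m.depth[members, j]
        a_mean = float((m.conversion[members, j] * w).sum() / max(w.sum(), 1.0))
        lo, hi, p_clonal = _pooled_band(alt_sum, depth_sum, a_mean)
        point = float(np.clip(res.cluster_ccfs[k, j], 0.0, 1.0))
        ccf[pop] = point
        lo_d[pop], hi_d[pop] = float(lo), float(hi)
        clon[pop] = "clonal" if (p_clonal > 0.5 or lo > 0.9) else "subclonal"
    return MutationCluster(
        cluster_id=k, member_ids=[res.model.mutation_ids[i] for i in members],
        member_rows=members, size=int(members.size),
        ccf=ccf, ci_low=lo_d, ci_high=hi_d, clonality=clon,
    )


# ---------------------------------------------------------------------------
# Cluster filtering, clone tree, seeding
# ---------------------------------------------------------------------------

def filter_clusters(clusters: list[MutationCluster], min_size: int = 5):
    """Discard clusters with fewer than `min_size` mutations.

    Returns (kept clusters, unassigned mutation ids). Mutations of discarded
    clusters are reported unassigned, never forced into other clusters, so
    assigned + unassigned = total.
    """
    kept = [c for c in clusters if c.size >= min_size]
    unassigned = [mid for c in clusters if c.size < min_size for mid in c.member_ids]
    return kept, unassigned


@dataclass
class CloneTree:
    """Rooted tree of mutation clusters (edges parent -> child)."""

    nodes: dict                       # cluster_id -> MutationCluster
    edges: list                       # (parent_id, child_id)
    root: int
    populations: list
    violations: list = field(default_factory=list)
    orphans: list = field(default_factory=list)

    def children(self, node: int) -> list:
        return [c for p, c in self.edges if p == node]

    def parent(self, node: int):
        for p, c in self.edges:
            if c == node:
                return p
        return None

    def to_newick(self) -> str:
        def render(node):
            kids = sorted(self.children(node))
            label = f"C{node}:{self.nodes[node].size}"
            if not kids:
                return label
            return "(" + ",".join(render(c) for c in kids) + ")" + label
        return render(self.root) + ";"

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "edges": [[p, c] for p, c in self.edges],
            "clusters": {
                str(c.cluster_id): {
                    "size": c.size,
                    "ccf": {p: round(v, 4) for p, v in c.ccf.items()},
                    "clonality": c.clonality,
                }
                for c in self.nodes.values()
            },
            "violations": self.violations,
            "orphans": self.orphans,
        }


def build_clone_tree(clusters: list[MutationCluster], tol: float = 0.05,
                     root_threshold: float = 0.9) -> CloneTree:
    """Arrange clusters into a rooted clone tree by CCF containment.

    The root is the truncal cluster (CCF >= `root_threshold` in every
    population). Each other cluster attaches to its minimum containing
    superset: the cluster with the smallest total CCF whose CCF dominates the
    child's in *every* population (within `tol`). Clusters with no containing
    parent are flagged as orphans and attached to the root; violations of the
    per-population sum rule (children's CCFs exceeding the parent's by more
    than `tol`) are recorded, not silently repaired.
    """
    if not clusters:
        raise ValueError("no clusters to arrange")
    pops = list(clusters[0].ccf.keys())
    vec = {c.cluster_id: np.array([c.ccf[p] for p in pops]) for c in clusters}
    roots = [c for c in clusters if (vec[c.cluster_id] >= root_threshold).all()]
    if not roots:
        raise ValueError("no truncal cluster: no cluster is clonal in all populations")
    root = max(roots, key=lambda c: vec[c.cluster_id].sum()).cluster_id

    edges, orphans = [], []
    order = sorted(clusters, key=lambda c: -vec[c.cluster_id].sum())
    for c in order:
        cid = c.cluster_id
        if cid == root:
            continue
        candidates = []
        for d in clusters:
            did = d.cluster_id
            if did == cid:
                continue
            if (vec[did] + tol >= vec[cid]).all() and (
                    vec[did].sum() > vec[cid].sum()
                    or (vec[did].sum() == vec[cid].sum() and did < cid)):
                candidates.append(did)
        if candidates:
            parent = min(candidates, key=lambda d: vec[d].sum())
            edges.append((parent, cid))
        else:
            orphans.append(cid)
            edges.append((root, cid))

    violations = []
    nodes = {c.cluster_id: c for c in clusters}
    for pid in nodes:
        kids = [c for p, c in edges if p == pid]
        if not kids:
            continue
        for j, p in enumerate(pops):
            total = sum(vec[c][j] for c in kids)
            if total > vec[pid][j] + tol:
                violations.append(
                    f"sum rule: children of C{pid} total CCF {total:.2f} "
                    f"> {vec[pid][j]:.2f} + {tol} in {p}"
                )
    return CloneTree(nodes=nodes, edges=edges, root=root, populations=pops,
                     violations=violations, orphans=orphans)


@dataclass
class SeedingAssignment:
    """Metastasis -> primary-population origin map with per-call evidence."""

    assignments: dict            # metastasis -> primary id or None
    evidence: dict               # metastasis -> dict
    unresolved: list

    def to_dict(self) -> dict:
        return {"assignments": self.assignments, "evidence": self.evidence,
                "unresolved": self.unresolved}


def infer_seeding(clusters: list[MutationCluster], sites: dict,
                  cnv_correlation: pd.DataFrame | None = None,
                  presence_threshold: float = 0.1) -> SeedingAssignment:
    """Assign each metastatic population to its primary-site origin.

    For metastasis M, each primary P is scored by the number of clusters
    present (CCF > `presence_threshold`) in both M and P but in no other
    primary — exclusively shared lineage. The highest score wins; ties and
    zero-evidence cases fall back to the highest CNV Pearson correlation when
    a correlation matrix is supplied, else the metastasis is flagged
    unresolved.
    """
    primaries = [p for p, s in sites.items() if s == "primary"]
    mets = [p for p, s in sites.items() if s == "metastasis"]
    if not primaries:
        raise ValueError("need at least one primary-site population")
    assignments, evidence, unresolved = {}, {}, []
    for met in mets:
        scores = {}
        shared_counts = {}
        for prim in primaries:
            n_excl, n_mut = 0, 0
            for c in clusters:
                if c.ccf.get(met, 0) <= presence_threshold:
                    continue
                if c.ccf.get(prim, 0) <= presence_threshold:
                    continue
                others = [q for q in primaries if q != prim]
                if all(c.ccf.get(q, 0) <= presence_threshold for q in others):
                    n_excl += 1
                    n_mut += c.size
            scores[prim] = n_excl
            shared_counts[prim] = n_mut
        best = max(scores.values()) if scores else 0
        winners = [p for p, s in scores.items() if s == best]
        ev = {"exclusive_cluster_scores": scores,
              "exclusive_mutation_counts": shared_counts, "used_cnv_tiebreak": False}
        if len(primaries) == 1:
            assignments[met] = primaries[0]
        elif len(winners) == 1 and best > 0:
            assignments[met] = winners[0]
        elif cnv_correlation is not None and met in cnv_correlation.index:
            pool = winners if best > 0 else primaries
            corr = {p: float(cnv_correlation.loc[met, p]) for p in pool}
            assignments[met] = max(corr, key=corr.get)
            ev["used_cnv_tiebreak"] = True
            ev["cnv_correlation"] = corr
        else:
            assignments[met] = None
            unresolved.append(met)
        evidence[met] = ev
    return SeedingAssignment(assignments=assignments, evidence=evidence,
                             unresolved=unresolved)


def ccf_trace(clusters: list[MutationCluster], population_order) -> pd.DataFrame:
    """Per-cluster CCF-vs-population series with pooled 95% bands, ordered for
    trace plotting. Absent clusters sit at 0 with a band touching 0."""
    rows = []
    for c in clusters:
        for pop in population_order:
            rows.append({
                "cluster": c.cluster_id, "population": pop,
                "ccf": c.ccf[pop], "ci_low": c.ci_low[pop], "ci_high": c.ci_high[pop],
                "clonality": c.clonality[pop], "size": c.size,
            })
    return pd.DataFrame(rows)
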
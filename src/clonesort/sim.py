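"""Synthetic polygenomic-tumor generator with full ground truth.

Emulates the data produced by multiparameter ploidy sorting followed by
whole-exome sequencing: 2-4 sorted tumor populations per patient with
distinct ploidies and purities, a rooted tree of mutation clusters with
per-population cancer cell fractions (CCFs), binomial read sampling at
configurable depth, signature-driven trinucleotide contexts, per-population
copy-number profiles, and per-biopsy FACS event tables (DAPI + marker
intensity per nucleus).

The generative read model at a mutation with CCF c in a population of
post-sort purity p, tumor copy number CN_t and multiplicity m is

    expected VAF = m * c * p / (p * CN_t + (1 - p) * 2)
    depth ~ Poisson(depth_mean), alt ~ Binomial(depth, expected VAF)

DAPI intensities are log-normal, centred so the geometric mean is exactly
proportional to ploidy; a configurable fraction of nuclei sit in G2/M at
twice the G0/G1 signal. All randomness flows from a single integer seed, so
fixed seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._genome import DEFAULT_GENOME
from .signatures import SBS96_CHANNELS, channel_ref_alt, toy_reference

_CCF_TOL = 1e-9


@dataclass(frozen=True)
class PopulationSpec:
    """One sorted tumor population to simulate."""

    name: str
    site: str                    # "primary" | "metastasis"
    biopsy: str
    ploidy: float
    purity_presort: float
    purity_postsort: float
    marker_rate: float = 0.98    # fraction of tumor nuclei that stain positive

    def __post_init__(self):
        if self.site not in ("primary", "metastasis"):
            raise ValueError(f"site must be primary|metastasis, got {self.site!r}")
        if not 1.5 <= self.ploidy <= 4.5:
            raise ValueError("ploidy must lie in [1.5, 4.5]")
        for v in (self.purity_presort, self.purity_postsort, self.marker_rate):
            if not 0.0 < v <= 1.0:
                raise ValueError("purities and marker rate must lie in (0, 1]")


@dataclass(frozen=True)
class ClusterSpec:
    """A mutation cluster: per-population true CCF vector + size.

    ``parent`` indexes the parent cluster in SimConfig.clusters (None only for
    the truncal root, index 0). ``signature_mix`` overrides the config-level
    mixture for this branch.
    """

    ccf: tuple
    n_mutations: int
    parent: int | None = None
    signature_mix: dict | None = None
    drivers: tuple = ()


@dataclass
class SimConfig:
    patient_id: str
    seed: int
    populations: list
    clusters: list
    depth_mean: float = 150.0
    facs_cv: float = 0.05
    g2m_fraction: float = 0.08
    n_facs_events: int = 10_000
    signature_mix: dict = field(default_factory=lambda: {"UV": 0.75, "flat": 0.25})
    cn_profiles: dict | None = None       # population -> segment DataFrame
    seeding_truth: dict = field(default_factory=dict)
    nonsynonymous_rate: float = 0.7

    def validate(self) -> None:
        if len(self.populations) < 2:
            raise ValueError("need at least 2 populations")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.facs_cv <= 0:
            raise ValueError("facs_cv must be positive")
        npop = len(self.populations)
        primaries = {p.name for p in self.populations if p.site == "primary"}
        for met, prim in self.seeding_truth.items():
            if prim not in primaries:
                raise ValueError(f"seeding truth maps {met} to non-primary {prim}")
        for i, cl in enumerate(self.clusters):
            ccf = np.asarray(cl.ccf, dtype=float)
            if ccf.shape != (npop,):
                raise ValueError(f"cluster {i}: CCF vector length != #populations")
            if (ccf < 0).any() or (ccf > 1).any():
                raise ValueError(f"cluster {i}: CCFs must lie in [0, 1]")
            if i == 0:
                if cl.parent is not None:
                    raise ValueError("cluster 0 must be the truncal root (parent None)")
                if not np.allclose(ccf, 1.0):
                    raise ValueError("truncal cluster must have CCF 1 in every population")
            else:
                if cl.parent is None or not 0 <= cl.parent < i:
                    raise ValueError(f"cluster {i}: parent must be an earlier cluster index")
                parent_ccf = np.asarray(self.clusters[cl.parent].ccf, dtype=float)
                if (ccf > parent_ccf + _CCF_TOL).any():
                    raise ValueError(
                        f"containment violated: cluster {i} exceeds its parent "
                        f"{cl.parent} in some population"
                    )
            mix = cl.signature_mix or self.signature_mix
            _check_mix(mix)

    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]


def _check_mix(mix: dict) -> None:
    w = np.array(list(mix.values()), dtype=float)
    if (w < 0).any():
        raise ValueError("signature weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"signature weights must sum to 1, got {w.sum()}")


@dataclass
class SimTruth:
    """Ground truth accompanying one simulated patient."""

    tree: dict                   # cluster index -> parent index (root maps to None)
    assignments: np.ndarray      # per-mutation cluster index
    seeding: dict                # metastasis population -> primary population
    ploidy: dict
    purity: dict
    signature_mix: dict          # cluster index -> mixture
    cluster_ccfs: np.ndarray     # (K, P)
    populations: list


@dataclass
class SimResult:
    config: SimConfig
    variants: pd.DataFrame       # wide table: alt_<pop>, dp_<pop>, context, gene, ...
    cn_profiles: dict            # population -> segment DataFrame
    facs: dict                   # biopsy -> event DataFrame
    truth: SimTruth


# ---------------------------------------------------------------------------
# FACS event simulation
# ---------------------------------------------------------------------------

def biopsy_event_fractions(presort_purities) -> np.ndarray:
    """Mixture fractions (tumor populations..., normal) consistent with the
    per-population pre-sort purity definition purity_i = e_i / (e_i + e_n)."""
    p = np.asarray(list(presort_purities), dtype=float)
    if (p <= 0).any() or (p >= 1).any():
        raise ValueError("pre-sort purities must lie in (0, 1) to define a mixture")
    rel = p / (1 - p)                       # e_i / e_n
    total = rel.sum() + 1.0
    return np.append(rel, 1.0) / total


def simulate_facs_events(populations, n_events: int = 10_000, facs_cv: float = 0.05,
                         g2m_fraction: float = 0.08, seed=None,
                         dapi_unit: float = 100.0, marker_rate: float = 0.98) -> pd.DataFrame:
    """Simulate one biopsy's FACS event table.

    Parameters
    ----------
    populations : list of (label, ploidy, event_fraction, marker_positive)
        tuples; fractions must sum to 1 (a diploid marker-negative normal
        population is typically the last entry).
    seed : int or numpy Generator.

    DAPI per nucleus is log-normal with geometric mean ``ploidy * dapi_unit``
    and the given coefficient of variation; a ``g2m_fraction`` of nuclei carry
    twice that signal (G2/M). Marker intensity is bimodal by tumor/normal
    label. Returns a DataFrame with event_id, dapi, marker, population
    (gate-truth label) and is_g2m columns.
    """
    if facs_cv <= 0:
        raise ValueError("facs_cv must be positive")
    if n_events < 100:
        raise ValueError("need at least 100 events")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [p[0] for p in populations]
    ploidies = np.array([p[1] for p in populations], dtype=float)
    fracs = np.array([p[2] for p in populations], dtype=float)
    positive = np.array([bool(p[3]) for p in populations])
    if abs(fracs.sum() - 1.0) > 1e-6:
        raise ValueError("event fractions must sum to 1")

    which = rng.choice(len(populations), size=n_events, p=fracs)
    sigma = np.sqrt(np.log1p(facs_cv ** 2))
    # mu = log(geometric mean): geometric means stay exactly ploidy-proportional
    dapi = np.exp(np.log(ploidies[which] * dapi_unit) + sigma * rng.standard_normal(n_events))
    is_g2m = rng.random(n_events) < g2m_fraction
    dapi = np.where(is_g2m, 2.0 * dapi, dapi)

    stains = np.where(positive[which], rng.random(n_events) < marker_rate, False)
    marker_mu = np.where(stains, np.log(1000.0), np.log(50.0))
    marker = np.exp(marker_mu + 0.35 * rng.standard_normal(n_events))

    return pd.DataFrame({
        "event_id": np.arange(n_events),
        "dapi": dapi,
        "marker": marker,
        "population": [labels[i] for i in which],
        "is_g2m": is_g2m,
    })


# ---------------------------------------------------------------------------
# Mutation context simulation
# ---------------------------------------------------------------------------

def _mix_probs(mix: dict, reference: pd.DataFrame) -> np.ndarray:
    _check_mix(mix)
    probs = np.zeros(96)
    for name, w in mix.items():
        if name not in reference.columns:
            raise ValueError(f"signature {name!r} not in reference")
        probs += w * reference[name].to_numpy(dtype=float)
    return probs / probs.sum()


def simulate_signature_contexts(n_mutations: int, signature_mix: dict,
                                reference: pd.DataFrame | None = None,
                                seed=None) -> np.ndarray:
    """Multinomial 96-channel context counts from a signature mixture.

    Counts sum exactly to n_mutations; n_mutations = 0 gives an all-zero
    vector.
    """
    reference = toy_reference() if reference is None else reference
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    probs = _mix_probs(signature_mix, reference)
    if n_mutations == 0:
        return np.zeros(96, dtype=int)
    return rng.multinomial(n_mutations, probs)


def _sample_channels(n: int, mix: dict, reference: pd.DataFrame, rng) -> list[str]:
    probs = _mix_probs(mix, reference)
    idx = rng.choice(96, size=n, p=probs)
    return [SBS96_CHANNELS[i] for i in idx]


# ---------------------------------------------------------------------------
# Copy-number profile helpers
# ---------------------------------------------------------------------------

def flat_cn_profile(ploidy: float, purity: float = 1.0,
                    genome: dict | None = None) -> pd.DataFrame:
    """One segment per chromosome at the rounded population ploidy."""
    genome = genome or DEFAULT_GENOME
    cn = int(round(ploidy))
    rows = [{"chrom": c, "start": 0, "end": ln, "total_cn": cn,
             "minor_cn": min(1, cn // 2)} for c, ln in genome.items()]
    df = pd.DataFrame(rows)
    return _with_log_ratio(df, ploidy)


def _with_log_ratio(segments: pd.DataFrame, ploidy: float) -> pd.DataFrame:
    df = segments.copy()
    df["log_ratio"] = np.log2(np.maximum(df["total_cn"].to_numpy(float), 0.5) / ploidy)
    return df


def alter_profile(profile: pd.DataFrame, ploidy: float, events) -> pd.DataFrame:
    """Apply (chrom, start, end, total_cn, minor_cn) events onto a profile,
    splitting segments at event boundaries (half-open semantics)."""
    segs = profile.drop(columns="log_ratio").to_dict("records")
    for chrom, start, end, cn, minor in events:
        new = []
        for s in segs:
            if s["chrom"] != chrom or s["end"] <= start or end <= s["start"]:
                new.append(s)
                continue
            if s["start"] < start:
                new.append({**s, "end": start})
            new.append({"chrom": chrom, "start": max(s["start"], start),
                        "end": min(s["end"], end), "total_cn": cn, "minor_cn": minor})
            if end < s["end"]:
                new.append({**s, "start": end})
        segs = new
    df = pd.DataFrame(segs).sort_values(["chrom", "start"]).reset_index(drop=True)
    return _with_log_ratio(df, ploidy)


def _profile_lookup_arrays(profile: pd.DataFrame) -> dict:
    by_chrom = {}
    for chrom, grp in profile.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        by_chrom[chrom] = (g["start"].to_numpy(), g["end"].to_numpy(),
                           g["total_cn"].to_numpy(), g["minor_cn"].to_numpy())
    return by_chrom


def cn_lookup_from_profiles(profiles: dict):
    """Callable ``(pop, chrom, pos) -> (total_cn, minor_cn)`` over segment
    tables; positions outside any segment fall back to diploid (2, 1)."""
    tables = {pop: _profile_lookup_arrays(df) for pop, df in profiles.items()}

    def lookup(pop, chrom, pos):
        arrs = tables.get(pop, {}).get(chrom)
        if arrs is None:
            return (2, 1)
        starts, ends, cn, minor = arrs
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos < ends[i]:
            return (int(cn[i]), int(minor[i]))
        return (2, 1)

    return lookup


# ---------------------------------------------------------------------------
# Patient simulation
# ---------------------------------------------------------------------------

def simulate_patient(config: SimConfig, reference: pd.DataFrame | None = None) -> SimResult:
    """Generate one patient's full synthetic dataset + ground truth."""
    config.validate()
    reference = toy_reference() if reference is None else reference
    rng = np.random.default_rng(config.seed)
    pops = config.population_names()
    specs = {p.name: p for p in config.populations}

    # copy-number profiles
    if config.cn_profiles is not None:
        profiles = config.cn_profiles
    else:
        profiles = {p.name: flat_cn_profile(p.ploidy) for p in config.populations}
    lookup = cn_lookup_from_profiles(profiles)

    # mutation positions: unique (chrom, pos) across the exome-wide genome
    n_total = sum(cl.n_mutations for cl in config.clusters)
    chroms = list(DEFAULT_GENOME)
    weights = np.array([DEFAULT_GENOME[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    seen, positions = set(), []
    while len(positions) < n_total:
        c = chroms[rng.choice(len(chroms), p=weights)]
        x = int(rng.integers(0, DEFAULT_GENOME[c]))
        if (c, x) not in seen:
            seen.add((c, x))
            positions.append((c, x))

    rows, assignments, mix_by_cluster = [], [], {}
    gene_counter = 0
    pos_iter = iter(positions)
    for k, cl in enumerate(config.clusters):
        mix = cl.signature_mix or config.signature_mix
        mix_by_cluster[k] = dict(mix)
        channels = _sample_channels(cl.n_mutations, mix, reference, rng)
        for j in range(cl.n_mutations):
            chrom, pos = next(pos_iter)
            ch = channels[j]
            ref_base, alt_base = channel_ref_alt(ch)
            if j < len(cl.drivers):
                gene, effect = cl.drivers[j], "non-synonymous"
            else:
                gene_counter += 1
                gene = f"GENE{gene_counter:05d}"
                effect = ("non-synonymous"
                          if rng.random() < config.nonsynonymous_rate else "synonymous")
            row = {"chrom": chrom, "pos": pos, "ref": ref_base, "alt": alt_base,
                   "gene": gene, "effect": effect, "context": ch}
            for p_i, pop in enumerate(pops):
                spec = specs[pop]
                ccf = float(cl.ccf[p_i])
                cn_t, _ = lookup(pop, chrom, pos)
                pur = spec.purity_postsort
                vaf = ccf * pur / (pur * cn_t + (1 - pur) * 2.0) if cn_t > 0 else 0.0
                depth = max(1, int(rng.poisson(config.depth_mean)))
                alt = int(rng.binomial(depth, min(vaf, 1.0)))
                row[f"alt_{pop}"] = alt
                row[f"dp_{pop}"] = depth
            rows.append(row)
            assignments.append(k)

    variants = pd.DataFrame(rows)
    variants.index = pd.MultiIndex.from_frame(variants[["chrom", "pos", "ref", "alt"]])

    # FACS event tables, one per biopsy
    facs = {}
    for biopsy in dict.fromkeys(p.biopsy for p in config.populations):
        members = [p for p in config.populations if p.biopsy == biopsy]
        fracs = biopsy_event_fractions([p.purity_presort for p in members])
        entries = [(p.name, p.ploidy, fracs[i], True) for i, p in enumerate(members)]
        entries.append(("normal", 2.0, fracs[-1], False))
        facs[biopsy] = simulate_facs_events(
            entries, n_events=config.n_facs_events, facs_cv=config.facs_cv,
            g2m_fraction=config.g2m_fraction, seed=rng,
            marker_rate=members[0].marker_rate,
        )

    truth = SimTruth(
        tree={k: cl.parent for k, cl in enumerate(config.clusters)},
        assignments=np.array(assignments),
        seeding=dict(config.seeding_truth),
        ploidy={p.name: p.ploidy for p in config.populations},
        purity={p.name: p.purity_postsort for p in config.populations},
        signature_mix=mix_by_cluster,
        cluster_ccfs=np.array([cl.ccf for cl in config.clusters], dtype=float),
        populations=pops,
    )
    return SimResult(config=config, variants=variants, cn_profiles=profiles,
                     facs=facs, truth=truth)


# ---------------------------------------------------------------------------
# Study-like presets
# ---------------------------------------------------------------------------

def _scaled(n: int, scale: float) -> int:
    return max(6, int(round(n * scale)))


def patient1_config(seed: int = 1, scale: float = 1.0, depth_mean: float = 150.0) -> SimConfig:
    """A polygenomic-primary patient: two primary-site tumor populations with
    different ploidies, a skin and a lymph-node metastasis, each metastasis
    seeded by a different primary population. Cluster CCF patterns follow the
    published clone-tree structure (truncal cluster plus a 1PST2/1MT1 lineage
    and a 1PST1/1MT2 lineage); ``scale`` shrinks cluster sizes for fast
    simulation studies without changing the topology."""
    pops = [
        PopulationSpec("1PST1", "primary", "1PST", 1.7, 0.19, 0.88),
        PopulationSpec("1PST2", "primary", "1PST", 2.7, 0.41, 0.95),
        PopulationSpec("1MT1", "metastasis", "1MT1", 2.6, 0.80, 0.91),
        PopulationSpec("1MT2", "metastasis", "1MT2", 2.7, 0.40, 0.93),
    ]
    s = scale
    clusters = [
        ClusterSpec((1, 1, 1, 1), _scaled(1513, s), None,
                    drivers=("KIT", "MECOM", "NRAS", "KMT2D", "TP53")),
        ClusterSpec((1, 1, 1, 0), _scaled(298, s), 0, drivers=("COL5A1",)),
        ClusterSpec((0, 1, 1, 0), _scaled(156, s), 1),
        ClusterSpec((1, 0, 0, 1), _scaled(199, s), 0),
        ClusterSpec((0.45, 0, 0, 0.6), _scaled(34, s), 3),
        ClusterSpec((0.3, 0, 0, 0.35), _scaled(227, s), 4),
    ]
    profiles = _patient1_cn_profiles()
    return SimConfig(
        patient_id="P1", seed=seed, populations=pops, clusters=clusters,
        depth_mean=depth_mean, cn_profiles=profiles,
        seeding_truth={"1MT1": "1PST2", "1MT2": "1PST1"},
    )


def _patient1_cn_profiles() -> dict:
    """CN profiles engineered so 1MT1 correlates with 1PST2 and 1MT2 with
    1PST1, mirroring the seeding structure."""
    lineage_a = [("chr1", 0, 120_000_000, 3, 1), ("chr6", 0, 171_000_000, 3, 1),
                 ("chr7", 0, 159_000_000, 4, 2), ("chr8", 40_000_000, 145_000_000, 3, 1)]
    lineage_b = [("chr9", 0, 138_000_000, 1, 0), ("chr10", 0, 134_000_000, 1, 0),
                 ("chr4", 0, 95_000_000, 1, 0)]
    out = {}
    for name, ploidy, events, private in [
        ("1PST1", 1.7, lineage_b, [("chr13", 0, 57_000_000, 1, 0)]),
        ("1PST2", 2.7, lineage_a, [("chr15", 0, 51_000_000, 4, 2)]),
        ("1MT1", 2.6, lineage_a, [("chr17", 41_500_000, 83_000_000, 4, 2)]),
        ("1MT2", 2.7, lineage_b, [("chr20", 0, 32_000_000, 3, 1)]),
    ]:
        base = flat_cn_profile(ploidy)
        out[name] = alter_profile(base, ploidy, events + private)
    return out


def patient2_config(seed: int = 2, scale: float = 1.0, depth_mean: float = 150.0) -> SimConfig:
    """A near-diploid monogenomic patient: primary and lymph-node metastasis of
    the same ploidy sharing most mutations, plus a small metastasis-specific
    subclone."""
    pops = [
        PopulationSpec("2PST", "primary", "2PST", 1.9, 0.80, 0.88),
        PopulationSpec("2MT", "metastasis", "2MT", 1.9, 0.88, 0.96),
    ]
    s = scale
    clusters = [
        ClusterSpec((1, 1), _scaled(832, s), None, drivers=("NRAS", "NF1", "KMT2D")),
        ClusterSpec((0.6, 0.7), _scaled(163, s), 0),
        ClusterSpec((0.5, 0), _scaled(63, s), 0),
        ClusterSpec((0, 0.4), _scaled(14, s), 0),
    ]
    shared = [("chr1", 0, 100_000_000, 3, 1), ("chr9", 0, 138_000_000, 1, 0),
              ("chr10", 0, 134_000_000, 1, 0)]
    profiles = {
        "2PST": alter_profile(flat_cn_profile(1.9), 1.9, shared),
        "2MT": alter_profile(flat_cn_profile(1.9), 1.9,
                             shared + [("chr16", 0, 45_000_000, 3, 1)]),
    }
    return SimConfig(
        patient_id="P2", seed=seed, populations=pops, clusters=clusters,
        depth_mean=depth_mean, cn_profiles=profiles,
        seeding_truth={"2MT": "2PST"},
    )


def patient3_config(seed: int = 3, scale: float = 1.0, depth_mean: float = 150.0) -> SimConfig:
    """A chemotherapy-exposed patient: UV-dominated trunk, a metastasis with a
    large private mutation load carrying platinum/alkylating signatures, and
    homozygous deletions (9p21, 11q13, 11p15) private to the primary."""
    pops = [
        PopulationSpec("3PST", "primary", "3PST", 3.0, 0.87, 0.91),
        PopulationSpec("3MT", "metastasis", "3MT", 3.1, 0.78, 0.87),
    ]
    chemo = {"platinum": 0.5, "alkylating": 0.3, "UV": 0.2}
    s = scale
    clusters = [
        ClusterSpec((1, 1), _scaled(330, s), None, drivers=("BRAF", "PPP6C")),
        ClusterSpec((0, 1), _scaled(9, s), 0, signature_mix=chemo),
        ClusterSpec((0.6, 0.5), _scaled(21, s), 0),
        ClusterSpec((0.5, 0), _scaled(10, s), 0),
        ClusterSpec((0, 0.8), _scaled(804, s), 1, signature_mix=chemo),
        ClusterSpec((0.6, 0), max(2, int(round(2 * s))), 0),
    ]
    base3 = flat_cn_profile(3.0)
    pst = alter_profile(base3, 3.0, [
        ("chr9", 21_000_000, 22_500_000, 0, 0),     # 9p21: CDKN2A/MTAP
        ("chr11", 65_000_000, 66_200_000, 0, 0),    # 11q13: OVOL1
        ("chr11", 0, 1_000_000, 0, 0),              # 11p15: HRAS
    ])
    mt = alter_profile(flat_cn_profile(3.1), 3.1, [("chr5", 0, 50_000_000, 4, 2)])
    return SimConfig(
        patient_id="P3", seed=seed, populations=pops, clusters=clusters,
        depth_mean=depth_mean, cn_profiles={"3PST": pst, "3MT": mt},
        seeding_truth={"3MT": "3PST"},
    )


def driver_clonality_example():
    """A 14-driver worked example over the eight sorted populations.

    Encodes a cohort-style driver landscape: five truncal drivers in the
    polygenomic patient, shared drivers in the monogenomic patients, and four
    driver mutations that are subclonal (or private) somewhere — so 10 of the
    14 driver mutations are clonal in every population where they appear.
    Returns (variants, clonality) frames in the wide-table and clonality-label
    conventions.
    """
    pops = ["1PST1", "1PST2", "1MT1", "1MT2", "2PST", "2MT", "3PST", "3MT"]
    # gene, populations present, populations where subclonal
    spec = [
        ("KIT", pops[:4], []), ("MECOM", pops[:4], []), ("NRAS", pops[:4], []),
        ("KMT2D", pops[:4], []), ("TP53", pops[:4], []),
        ("NRAS", ["2PST", "2MT"], []), ("NF1", ["2PST", "2MT"], []),
        ("KMT2D", ["2PST", "2MT"], []),
        ("BRAF", ["3PST", "3MT"], []), ("PPP6C", ["3PST", "3MT"], []),
        ("COL5A1", ["1PST1", "1PST2", "1MT1"], ["1PST1"]),
        ("CTNNB1", ["1MT2"], ["1MT2"]),
        ("ARID2", ["2PST", "2MT"], ["2MT"]),
        ("RAC1", ["3MT"], ["3MT"]),
    ]
    rows, clon_rows = [], []
    for i, (gene, present, subclonal) in enumerate(spec):
        row = {"chrom": "chr1", "pos": 1000 + i, "ref": "C", "alt": "T",
               "gene": gene, "effect": "non-synonymous", "context": "T[C>T]A"}
        clon = {}
        for p in pops:
            row[f"alt_{p}"] = 50 if p in present else 0
            row[f"dp_{p}"] = 100
            if p in present:
                clon[p] = "subclonal" if p in subclonal else "clonal"
        rows.append(row)
        clon_rows.append(clon)
    variants = pd.DataFrame(rows)
    variants.index = pd.MultiIndex.from_frame(variants[["chrom", "pos", "ref", "alt"]])
    clonality = pd.DataFrame(clon_rows, index=variants.index)
    return variants, clonality


#: Post-sort (WES) and pre-sort (FACS) purities of the eight sorted
#: populations, in cohort order; inputs to the purity worked examples.
POSTSORT_PURITIES_PCT = (88, 95, 91, 93, 88, 96, 91, 87)
PRESORT_PURITIES_PCT = (19, 41, 80, 40, 80, 88, 87, 78)


#: Approximate GRCh38 intervals of the melanoma-relevant genes used in the
#: homozygous-deletion examples (0-based half-open).
MELANOMA_GENE_INTERVALS = pd.DataFrame([
    {"chrom": "chr9", "start": 21_802_635, "end": 21_941_115, "gene": "MTAP"},
    {"chrom": "chr9", "start": 21_967_752, "end": 21_995_043, "gene": "CDKN2A"},
    {"chrom": "chr11", "start": 65_787_022, "end": 65_797_219, "gene": "OVOL1"},
    {"chrom": "chr11", "start": 532_242, "end": 535_567, "gene": "HRAS"},
])
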
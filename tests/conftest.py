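import numpy as np
import pandas as pd
import pytest

from clonesort import sim as sim_mod
from clonesort.clones import CCFMixtureModel
from clonesort.signatures import toy_reference
from clonesort.variants import apply_filters


@pytest.fixture(scope="session")
def toy_ref():
    return toy_reference()


@pytest.fixture(scope="session")
def patient1_sim():
    """Quarter-scale polygenomic patient with ground truth (seed 7)."""
    cfg = sim_mod.patient1_config(seed=7, scale=0.25)
    return cfg, sim_mod.simulate_patient(cfg)


@pytest.fixture(scope="session")
def patient1_fit(patient1_sim):
    """Filtered variants + fitted CCF mixture for the quarter-scale patient."""
    cfg, res = patient1_sim
    retained, tally = apply_filters(res.variants)
    pops = cfg.population_names()
    purity = {p.name: p.purity_postsort for p in cfg.populations}
    lookup = sim_mod.cn_lookup_from_profiles(res.cn_profiles)
    model = CCFMixtureModel.from_variants(retained, pops, purity, lookup)
    results = model.fit(k_max=8, n_init=20, seed=7)
    return cfg, res, retained, results


def truth_labels_for(res, subset: pd.DataFrame) -> list:
    """Ground-truth cluster labels aligned to a (possibly filtered) table."""
    lut = {tuple(k): int(v) for k, v in zip(res.variants.index, res.truth.assignments)}
    return [lut[tuple(i)] for i in subset.index]


def wide_table(rows: dict, pops) -> pd.DataFrame:
    """Build a wide variant table from {id: {pop: (alt, dp)}} dicts."""
    out = []
    for i, (name, depths) in enumerate(rows.items()):
        row = {"chrom": "chr1", "pos": i, "ref": "A", "alt": "T",
               "gene": name, "effect": "non-synonymous", "context": None}
        for p in pops:
            a, d = depths.get(p, (0, 100))
            row[f"alt_{p}"] = a
            row[f"dp_{p}"] = d
        out.append(row)
    df = pd.DataFrame(out)
    df.index = pd.MultiIndex.from_frame(df[["chrom", "pos", "ref", "alt"]])
    return df


@pytest.fixture()
def cascade_table():
    """Six variants engineered to exercise each filtering rule exactly once:
    three survive (primary pass, relaxed-rescue pass, relaxed + primary),
    three fall (VAF floor, read floor, panel of normals)."""
    df = wide_table({
        "primary_pass": {"A": (10, 100)},                      # retained in A
        "vaf_floor": {"A": (10, 2000)},                        # VAF 0.5% -> out
        "relaxed_pair": {"A": (2, 40), "B": (8, 80)},          # retained in both
        "reads_floor": {"A": (2, 40)},                         # 5% but 2 reads, no sibling
        "pon_hit": {"A": (50, 100)},                           # killed by the panel
        "relaxed_second": {"A": (2, 200), "B": (4, 20)},       # retained in both
    }, ["A", "B"])
    pon = pd.Series(0, index=df.index)
    pon.loc[("chr1", 4, "A", "T")] = 3
    return df, pon


def make_shared_private_table(n_shared: int, n_private_a: int, n_private_b: int):
    """Two-population table with exact shared/private counts."""
    n = n_shared + n_private_a + n_private_b
    df = pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(n), "ref": "A", "alt": "T",
        "gene": "G", "effect": "non-synonymous", "context": None,
    })
    in_a = np.zeros(n, bool)
    in_b = np.zeros(n, bool)
    in_a[:n_shared + n_private_a] = True
    in_b[:n_shared] = True
    in_b[n_shared + n_private_a:] = True
    df["alt_A"] = np.where(in_a, 40, 0)
    df["dp_A"] = 100
    df["alt_B"] = np.where(in_b, 40, 0)
    df["dp_B"] = 100
    df.index = pd.MultiIndex.from_frame(df[["chrom", "pos", "ref", "alt"]])
    return df
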
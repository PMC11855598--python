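"""Cancer-cell-fraction estimation and clonal/subclonal classification.

For a mutation observed at variant allele frequency (VAF) f in a sample of
purity p, with tumor total copy number CN_t and normal copy number CN_n at
the locus, and carried on m allele copies per mutated cell, the expected VAF
is

    f = m * CCF * p / (p * CN_t + (1 - p) * CN_n)

which inverts in closed form to

    CCF = f * (p * CN_t + (1 - p) * CN_n) / (p * m).

Multiplicity m is estimated by rounding the allele-count implied by the VAF.
Uncertainty is propagated from a Jeffreys Beta(alt + 1/2, ref + 1/2)
posterior on the VAF through the (linear, monotone) CCF map. A mutation is
called clonal when its posterior probability of CCF >= 0.9 exceeds 0.5 or the
lower bound of its 95% CCF interval exceeds 0.9; otherwise subclonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

#: CCF values above 1 can arise from sampling noise or multiplicity
#: misestimates; the raw value is kept for diagnostics but classification and
#: clustering use the value clipped to this ceiling and then capped at 1.
RAW_CCF_CEILING = 1.2


@dataclass
class CCFEstimate:
    mutation_id: object
    population_id: str
    multiplicity: int
    ccf: float              # capped at 1.0
    ccf_raw: float          # clipped to [0, RAW_CCF_CEILING]
    ci_low: float
    ci_high: float
    p_clonal: float
    label: str              # "clonal" | "subclonal"


def _check_params(purity, cn_tumor, multiplicity):
    purity = np.asarray(purity, dtype=float)
    if (purity <= 0).any() or (purity > 1).any():
        raise ValueError("purity must lie in (0, 1]")
    if (np.asarray(cn_tumor) < 0).any():
        raise ValueError("tumor copy number must be >= 0")
    if (np.asarray(multiplicity) < 1).any():
        raise ValueError("multiplicity must be >= 1")


def forward_vaf(ccf, purity, cn_tumor, cn_normal=2, multiplicity=1):
    """Expected VAF of a mutation at the given CCF (the generative direction)."""
    _check_params(purity, cn_tumor, multiplicity)
    denom = purity * np.asarray(cn_tumor, float) + (1 - purity) * np.asarray(cn_normal, float)
    return np.asarray(multiplicity, float) * np.asarray(ccf, float) * purity / denom


def compute_ccf(vaf, purity, cn_tumor, cn_normal=2, multiplicity=1, cap=True):
    """Closed-form CCF from VAF; vectorised over numpy inputs.

    With ``cap=True`` (default) the result is clipped to [0, 1.2] and then
    capped at 1.0 — the value used for classification and clustering. With
    ``cap=False`` the clipped-but-uncapped value is returned for diagnostics.
    """
    vaf = np.asarray(vaf, dtype=float)
    if (vaf < 0).any() or (vaf > 1).any():
        raise ValueError("VAF must lie in [0, 1]")
    _check_params(purity, cn_tumor, multiplicity)
    denom = np.asarray(multiplicity, float) * np.asarray(purity, float)
    if np.any(denom == 0):
        raise ValueError("purity * multiplicity must be positive")
    total_cn = np.asarray(purity, float) * np.asarray(cn_tumor, float) \
        + (1 - np.asarray(purity, float)) * np.asarray(cn_normal, float)
    raw = np.clip(vaf * total_cn / denom, 0.0, RAW_CCF_CEILING)
    out = np.minimum(raw, 1.0) if cap else raw
    return float(out) if out.ndim == 0 else out


def estimate_multiplicity(vaf, purity, cn_tumor, cn_normal=2):
    """Integer multiplicity m = clamp(round(VAF * total CN / purity), 1, CN_t).

    The quantity VAF * (p*CN_t + (1-p)*CN_n) / p is the expected number of
    mutated copies per tumor cell if the mutation were fully clonal; rounding
    it gives the maximum-likelihood integer multiplicity for clonal and
    near-clonal mutations. Deterministic.
    """
    vaf = np.asarray(vaf, dtype=float)
    _check_params(purity, cn_tumor, 1)
    purity = np.asarray(purity, float)
    cn_tumor = np.asarray(cn_tumor, float)
    total_cn = purity * cn_tumor + (1 - purity) * np.asarray(cn_normal, float)
    m = np.rint(vaf * total_cn / purity)
    m = np.clip(m, 1, np.maximum(1, np.rint(cn_tumor)))
    out = m.astype(int)
    return int(out) if out.ndim == 0 else out


def ccf_interval(alt, depth, purity, cn_tumor, cn_normal=2, multiplicity=1,
                 level=0.95):
    """Equal-tailed credible interval for CCF.

    A Jeffreys Beta(alt + 1/2, depth - alt + 1/2) posterior on the VAF is
    pushed through the monotone linear VAF -> CCF map and clipped/capped like
    the point estimate. Returns (lo, hi); vectorised.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if (depth < 1).any():
        raise ValueError("depth must be >= 1")
    if (alt < 0).any() or (alt > depth).any():
        raise ValueError("alt must lie in [0, depth]")
    a, b = alt + 0.5, depth - alt + 0.5
    tail = (1 - level) / 2
    v_lo = np.where(alt == 0, 0.0, beta_dist.ppf(tail, a, b))
    v_hi = np.where(alt == depth, 1.0, beta_dist.ppf(1 - tail, a, b))
    lo = compute_ccf(v_lo, purity, cn_tumor, cn_normal, multiplicity)
    hi = compute_ccf(v_hi, purity, cn_tumor, cn_normal, multiplicity)
    return lo, hi


def clonal_probability(alt, depth, purity, cn_tumor, cn_normal=2, multiplicity=1,
                       ccf_threshold=0.9):
    """Posterior probability that CCF >= `ccf_threshold` under the Jeffreys
    posterior on VAF."""
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    vaf_at_threshold = forward_vaf(ccf_threshold, purity, cn_tumor, cn_normal, multiplicity)
    return 1.0 - beta_dist.cdf(np.minimum(vaf_at_threshold, 1.0), alt + 0.5, depth - alt + 0.5)


def classify_clonal(p_clonal, ci_low, p_threshold=0.5, ci_low_threshold=0.9):
    """Clonal iff P(clonal) > 0.5 OR the 95% CI lower bound exceeds 0.9."""
    p_clonal = np.asarray(p_clonal, dtype=float)
    ci_low = np.asarray(ci_low, dtype=float)
    clonal = (p_clonal > p_threshold) | (ci_low > ci_low_threshold)
    out = np.where(clonal, "clonal", "subclonal")
    return str(out) if out.ndim == 0 else out


def estimate_purity_from_truncal(vafs, cn_tumor=2, cn_normal=2):
    """Post-sort purity from truncal heterozygous VAFs.

    Truncal mutations have CCF = 1 and (mostly) multiplicity 1, so
    f = p / (p*CN_t + (1-p)*CN_n) inverts to p = f*CN_n / (1 + f*CN_n - f*CN_t).
    The median over sites makes the estimate robust to the multiplicity > 1
    minority. Intended as a light-weight stand-in when no allele-specific CN
    fit is available.
    """
    vafs = np.asarray(vafs, dtype=float)
    if vafs.size == 0:
        raise ValueError("need at least one truncal VAF")
    cn_t = np.asarray(cn_tumor, dtype=float)
    p = vafs * cn_normal / (1.0 + vafs * cn_normal - vafs * cn_t)
    return float(np.clip(np.median(p), 0.01, 1.0))


def ccf_table(variants: pd.DataFrame, populations, purity: dict, cn_lookup=None,
              level=0.95, p_threshold=0.5, ci_low_threshold=0.9) -> pd.DataFrame:
    """Per-(mutation, population) CCF estimates for a wide variant table.

    Parameters
    ----------
    variants : DataFrame with ``alt_<pop>`` and ``dp_<pop>`` columns.
    populations : population ids to evaluate.
    purity : mapping population -> post-sort purity.
    cn_lookup : optional callable ``(pop, chrom, pos) -> (cn_total, cn_minor)``;
        defaults to diploid (2, 1) everywhere.

    Returns a tidy frame with one row per mutation x population (index of
    `variants` is used as the mutation id).
    """
    rows = []
    for pop in populations:
        alt = variants[f"alt_{pop}"].to_numpy(dtype=float)
        dp = variants[f"dp_{pop}"].to_numpy(dtype=float)
        dp_safe = np.maximum(dp, 1.0)
        vaf = np.where(dp > 0, alt / dp_safe, 0.0)
        if cn_lookup is None:
            cn_t = np.full(len(variants), 2.0)
        else:
            cn_t = np.array([
                float(cn_lookup(pop, c, p)[0])
                for c, p in zip(variants["chrom"], variants["pos"])
            ])
        p = purity[pop]
        m = estimate_multiplicity(vaf, p, cn_t)
        raw = compute_ccf(vaf, p, cn_t, 2, m, cap=False)
        point = np.minimum(raw, 1.0)
        lo, hi = ccf_interval(alt, dp_safe, p, cn_t, 2, m, level=level)
        p_cl = clonal_probability(alt, dp_safe, p, cn_t, 2, m, ccf_threshold=ci_low_threshold)
        label = classify_clonal(p_cl, lo, p_threshold, ci_low_threshold)
        rows.append(pd.DataFrame({
            "mutation_id": variants.index,
            "population": pop,
            "alt": alt.astype(int), "depth": dp.astype(int),
            "multiplicity": m, "ccf": point, "ccf_raw": raw,
            "ci_low": lo, "ci_high": hi, "p_clonal": p_cl, "label": label,
        }))
    return pd.concat(rows, ignore_index=True)
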
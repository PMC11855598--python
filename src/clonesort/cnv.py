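"""Copy-number category calls, profile correlation, and homozygous deletions.

Segments are consumed (never produced) as allele-specific copy-number tables
with 0-based half-open coordinates: chrom, start, end, total_cn, minor_cn,
log_ratio. Category calls are made relative to the population ploidy:

    total CN 0                         -> homozygous_deletion
    CN < round(ploidy)                 -> loss
    CN = round(ploidy)                 -> neutral
    round(ploidy) < CN < round(ploidy)+3 -> gain
    CN >= round(ploidy)+3              -> amplification

Profile similarity is the Pearson correlation of log ratios rasterised onto
fixed genomic bins (1 Mb default), computed pairwise on bins covered in both
profiles, with the two-sided p-value from the t-transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from ._genome import DEFAULT_GENOME

CATEGORIES = ("homozygous_deletion", "loss", "neutral", "gain", "amplification")
SEGMENT_COLUMNS = ["chrom", "start", "end", "total_cn", "minor_cn", "log_ratio"]


@dataclass
class CNSegmentProfile:
    """Per-population allele-specific copy-number segments."""

    population_id: str
    segments: pd.DataFrame
    ploidy: float

    def __post_init__(self):
        seg = self.segments
        missing = set(SEGMENT_COLUMNS) - set(seg.columns)
        if missing:
            raise ValueError(f"segment table missing columns {sorted(missing)}")
        if (seg["total_cn"] < 0).any() or (seg["minor_cn"] < 0).any():
            raise ValueError("copy numbers must be >= 0")
        if (seg["total_cn"] < seg["minor_cn"]).any():
            raise ValueError("total CN must be >= minor CN")
        for chrom, grp in seg.groupby("chrom"):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping segments on {chrom}")
        self.segments = seg.sort_values(["chrom", "start"]).reset_index(drop=True)


def call_categories(profile: CNSegmentProfile, amplification_offset: int = 3) -> pd.DataFrame:
    """Assign each segment exactly one CN category relative to ploidy."""
    seg = profile.segments.copy()
    cn = seg["total_cn"].to_numpy(dtype=float)
    if (cn < 0).any():
        raise ValueError("negative copy number")
    base = int(round(profile.ploidy))
    cat = np.where(cn == 0, "homozygous_deletion",
          np.where(cn < base, "loss",
          np.where(cn == base, "neutral",
          np.where(cn < base + amplification_offset, "gain", "amplification"))))
    seg["category"] = cat
    return seg


def _rasterize(profile: CNSegmentProfile, bin_size: int, genome: dict) -> np.ndarray:
    """Per-bin log ratio across the genome; NaN where no segment covers the bin
    midpoint."""
    chroms = list(genome)
    n_bins = [int(np.ceil(genome[c] / bin_size)) for c in chroms]
    offsets = dict(zip(chroms, np.cumsum([0] + n_bins[:-1])))
    out = np.full(sum(n_bins), np.nan)
    nb = dict(zip(chroms, n_bins))
    for _, s in profile.segments.iterrows():
        if s["chrom"] not in offsets:
            continue
        off = offsets[s["chrom"]]
        # bins whose midpoint falls inside [start, end)
        lo = max(int(np.ceil((s["start"] - bin_size / 2) / bin_size)), 0)
        hi = min(int(np.ceil((s["end"] - bin_size / 2) / bin_size)), nb[s["chrom"]])
        if hi > lo:
            out[off + lo: off + hi] = s["log_ratio"]
    return out


def correlation_matrix(profiles: list[CNSegmentProfile], bin_size: int = 1_000_000,
                       genome: dict | None = None):
    """Pairwise Pearson correlation of binned log-ratio profiles.

    Returns (R, p) DataFrames indexed by population id. Each pair is compared
    only on bins covered in both profiles; fewer than 2 shared bins raises.
    The diagonal is exactly 1 with p = 0.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    genome = genome or DEFAULT_GENOME
    names = [p.population_id for p in profiles]
    vecs = {p.population_id: _rasterize(p, bin_size, genome) for p in profiles}
    R = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    P = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = vecs[a], vecs[b]
            mask = ~np.isnan(va) & ~np.isnan(vb)
            if mask.sum() < 2:
                raise ValueError(f"profiles {a} and {b} share fewer than 2 covered bins")
            if np.ptp(va[mask]) == 0 or np.ptp(vb[mask]) == 0:
                r, pv = 0.0, 1.0  # a flat profile carries no correlation signal
            else:
                r, pv = pearsonr(va[mask], vb[mask])
            R.loc[a, b] = R.loc[b, a] = float(r)
            P.loc[a, b] = P.loc[b, a] = float(pv)
    return R, P


def find_homozygous_deletions(profile: CNSegmentProfile,
                              genes: pd.DataFrame) -> list[dict]:
    """Intersect CN-0 segments with gene intervals (0-based half-open).

    `genes` needs chrom/start/end/gene columns. Returns one entry per CN-0
    segment that overlaps at least one gene; abutting intervals (segment end
    == gene start) do not overlap.
    """
    out = []
    zero = profile.segments[profile.segments["total_cn"] == 0]
    for _, s in zero.iterrows():
        hit = genes[(genes["chrom"] == s["chrom"])
                    & (genes["start"] < s["end"]) & (s["start"] < genes["end"])]
        if len(hit):
            out.append({
                "chrom": s["chrom"], "start": int(s["start"]), "end": int(s["end"]),
                "genes": sorted(hit["gene"].tolist()),
            })
    return out
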
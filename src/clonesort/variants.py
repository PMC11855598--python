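"""Somatic variant model, the filtering cascade, driver annotation, TMB, and
shared/private summaries.

Variant tables are carried as wide pandas DataFrames, one row per variant,
indexed by ``(chrom, pos, ref, alt)``, with fixed columns
``chrom, pos, ref, alt, gene, effect, context`` plus per-population read
counts ``alt_<pop>`` (alt-supporting reads) and ``dp_<pop>`` (total depth).
``effect`` is one of ``synonymous | non-synonymous | other`` and is an input
annotation, not computed here.

The filtering cascade retains a variant in population p when
VAF_p >= 1% and alt_p >= 3 reads; the read cut-off is relaxed to 2 when the
variant independently passes the primary rule in at least one other sorted
population of the same patient. Variants seen in >= 2 samples of a panel of
normals are removed everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]
EFFECTS = ("synonymous", "non-synonymous", "other")


@dataclass(frozen=True)
class VariantRecord:
    """One somatic SNV/indel with per-population read support."""

    chrom: str
    pos: int                      # 0-based
    ref: str
    alt: str
    gene: str = ""
    effect: str = "other"
    context: str | None = None    # SBS96 channel, SNVs only
    depths: dict = None           # population -> (alt_reads, ref_reads)

    def __post_init__(self):
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect class {self.effect!r}")
        is_snv = len(self.ref) == 1 and len(self.alt) == 1
        if self.context is not None and not is_snv:
            raise ValueError("trinucleotide context is defined for SNVs only")
        for pop, (a, r) in (self.depths or {}).items():
            if a < 0 or r < 0:
                raise ValueError(f"negative depth for population {pop}")

    def vaf(self, population: str) -> float:
        a, r = self.depths[population]
        return a / (a + r) if (a + r) > 0 else 0.0


def records_to_frame(records: list[VariantRecord], populations) -> pd.DataFrame:
    """Assemble VariantRecords into the wide DataFrame convention."""
    rows = []
    for rec in records:
        row = {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
               "gene": rec.gene, "effect": rec.effect, "context": rec.context}
        for pop in populations:
            a, r = (rec.depths or {}).get(pop, (0, 0))
            row[f"alt_{pop}"] = a
            row[f"dp_{pop}"] = a + r
        rows.append(row)
    df = pd.DataFrame(rows)
    df.index = pd.MultiIndex.from_frame(df[VARIANT_KEY])
    return df


@dataclass
class FilterConfig:
    """Thresholds of the filtering cascade (defaults per the study design)."""

    vaf_min: float = 0.01
    min_alt_reads: int = 3
    shared_min_alt_reads: int = 2
    pon_max_hits: int = 1          # exclude when seen in >= pon_max_hits + 1 panel samples
    panel_size: int = 210          # metadata only
    count_mode: str = "alt"        # "alt": read cut-offs on alt reads; "total": on depth

    def __post_init__(self):
        if self.shared_min_alt_reads > self.min_alt_reads:
            raise ValueError("shared_min_alt_reads must be <= min_alt_reads")
        if self.count_mode not in ("alt", "total"):
            raise ValueError("count_mode must be 'alt' or 'total'")


def population_list(variants: pd.DataFrame) -> list[str]:
    return [c[4:] for c in variants.columns if c.startswith("alt_")]


def apply_filters(variants: pd.DataFrame, config: FilterConfig | None = None,
                  patient_populations: list[str] | None = None,
                  pon_hits=None) -> tuple[pd.DataFrame, dict]:
    """Run the filtering cascade over one patient's variant table.

    Parameters
    ----------
    variants : wide variant DataFrame (one patient).
    patient_populations : the sorted populations belonging to this patient;
        defaults to every population present in the table. Populations with
        read columns but absent from this list raise.
    pon_hits : optional mapping/Series variant-index -> number of
        panel-of-normals samples carrying the variant.

    Returns
    -------
    (retained, tally) : `retained` keeps rows passing in >= 1 population and
    gains boolean ``pass_<pop>`` columns; `tally` partitions every discarded
    row by the first matching rule (panel_of_normals, vaf_below_min,
    insufficient_alt_reads) and counts the retained rows, so the tally always
    sums to the input row count.
    """
    config = config or FilterConfig()
    table_pops = population_list(variants)
    pops = patient_populations or table_pops
    extra = set(table_pops) - set(pops)
    if extra:
        raise ValueError(f"populations {sorted(extra)} present in table but not in patient map")

    n = len(variants)
    dp = np.column_stack([variants[f"dp_{p}"].to_numpy(float) for p in pops])
    alt = np.column_stack([variants[f"alt_{p}"].to_numpy(float) for p in pops])
    if n and not (dp.max(axis=1) > 0).all():
        raise ValueError("every variant needs depth > 0 in at least one population")
    vaf = np.divide(alt, dp, out=np.zeros_like(alt), where=dp > 0)
    reads = alt if config.count_mode == "alt" else dp

    vaf_ok = vaf >= config.vaf_min
    primary = vaf_ok & (reads >= config.min_alt_reads)
    # relaxed read cut-off applies where the variant passes the primary rule
    # in some *other* population of the same patient
    elsewhere = primary.sum(axis=1, keepdims=True) - primary
    relaxed = vaf_ok & (reads >= config.shared_min_alt_reads) & (elsewhere >= 1)
    passes = primary | relaxed

    if pon_hits is not None:
        hits = pd.Series(pon_hits).reindex(variants.index).fillna(0).to_numpy(float)
        in_pon = hits > config.pon_max_hits
        passes = passes & ~in_pon[:, None]
    else:
        in_pon = np.zeros(n, dtype=bool)

    keep = passes.any(axis=1)
    tally = {
        "panel_of_normals": int(in_pon.sum()),
        "vaf_below_min": int((~in_pon & ~keep & ~vaf_ok.any(axis=1)).sum()),
        "insufficient_alt_reads": int((~in_pon & ~keep & vaf_ok.any(axis=1)).sum()),
        "retained": int(keep.sum()),
    }
    retained = variants.loc[keep].copy()
    for j, p in enumerate(pops):
        retained[f"pass_{p}"] = passes[keep, j]
    return retained, tally


def presence_matrix(variants: pd.DataFrame, populations=None) -> pd.DataFrame:
    """Binary presence/absence matrix (rows: variants, cols: populations).

    A variant is present in a population when it passed the filter there (if
    ``pass_`` columns exist) or, failing that, when it has any alt reads.
    """
    pops = populations or population_list(variants)
    cols = {}
    for p in pops:
        if f"pass_{p}" in variants.columns:
            cols[p] = variants[f"pass_{p}"].astype(int)
        else:
            cols[p] = (variants[f"alt_{p}"] > 0).astype(int)
    return pd.DataFrame(cols, index=variants.index)


def annotate_drivers(variants: pd.DataFrame, driver_genes,
                     clonality: pd.DataFrame | None = None):
    """Flag known-driver mutations and build the gene x population matrix.

    A variant is a driver hit iff its gene is in `driver_genes` and its effect
    class is non-synonymous. `clonality`, if given, is a DataFrame indexed
    like `variants` with one column per population holding
    ``clonal``/``subclonal``/NaN (absent); the matrix then distinguishes
    clonal from subclonal presence, and the summary reports how many driver
    mutations are clonal in every population where they are present.
    """
    driver_genes = set(driver_genes or [])
    flagged = variants.copy()
    flagged["is_driver"] = (flagged["gene"].isin(driver_genes)
                            & (flagged["effect"] == "non-synonymous"))
    drivers = flagged.loc[flagged["is_driver"]]
    pres = presence_matrix(drivers) if len(drivers) else pd.DataFrame()

    matrix_rows, n_clonal = {}, 0
    for idx, row in drivers.iterrows():
        cells = {}
        fully_clonal, present_somewhere = True, False
        for pop in pres.columns:
            if not pres.loc[idx, pop]:
                cells[pop] = "absent"
                continue
            present_somewhere = True
            if clonality is not None and idx in clonality.index:
                lab = clonality.loc[idx, pop]
                lab = lab if isinstance(lab, str) else "clonal"
            else:
                lab = "clonal"
            cells[pop] = lab
            if lab != "clonal":
                fully_clonal = False
        matrix_rows[(row["gene"], idx)] = cells
        if present_somewhere and fully_clonal:
            n_clonal += 1

    matrix = pd.DataFrame.from_dict(matrix_rows, orient="index").fillna("absent")
    n_driver = len(drivers)
    summary = {
        "n_drivers": n_driver,
        "n_clonal": n_clonal,
        "pct_clonal": round(100.0 * n_clonal / n_driver, 1) if n_driver else 0.0,
    }
    return flagged, matrix, summary


def tmb(variants: pd.DataFrame, population: str, callable_mb: float = 35.7) -> float:
    """Tumor mutational burden: somatic (synonymous + non-synonymous)
    mutations present in `population` per callable megabase, to 1 decimal."""
    if callable_mb <= 0:
        raise ValueError("callable megabases must be positive")
    coding = variants["effect"].isin(["synonymous", "non-synonymous"])
    if f"pass_{population}" in variants.columns:
        present = variants[f"pass_{population}"].astype(bool)
    else:
        present = variants[f"alt_{population}"] > 0
    return round(int((coding & present).sum()) / callable_mb, 1)


def shared_private_summary(variants: pd.DataFrame, populations=None) -> dict:
    """Counts/percentages of mutations shared by all, some, or one population.

    Each mutation is counted once per patient; percentages are of the total
    and rounded to 1 decimal.
    """
    pops = populations or population_list(variants)
    if len(pops) < 2:
        raise ValueError("shared/private summary needs >= 2 populations")
    pres = presence_matrix(variants, pops)
    npop = pres.sum(axis=1)
    total = int((npop > 0).sum())
    shared_all = int((npop == len(pops)).sum())
    private = int((npop == 1).sum())
    shared_some = total - shared_all - private

    def pct(x):
        return round(100.0 * x / total, 1) if total else 0.0

    return {
        "total": total,
        "shared_all": shared_all, "shared_all_pct": pct(shared_all),
        "shared_some": shared_some, "shared_some_pct": pct(shared_some),
        "private": private, "private_pct": pct(private),
    }
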
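"""Flow-sorting analysis: ploidy from DAPI geometric means, DNA-index
conversion, gate placement, and pre-sort purity from gate event fractions.

A biopsy's nuclei are stained with DAPI (DNA content) and a lineage marker
(SOX10 or S100 for melanoma). Tumor nuclei are marker-positive; their ploidy
N is estimated as twice the ratio of the geometric mean DAPI signal of the
tumor population to that of the marker-negative diploid (normal) population.
Pre-sort purity is the fraction of events falling in the tumor analysis gate
among events in either the tumor or the normal gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean, gaussian_kde


@dataclass(frozen=True)
class GateSpec:
    """A rectangular analysis gate in (marker, DAPI) space.

    ``marker_positive`` selects events above (True) or at/below (False) the
    marker threshold; ``dapi_low <= dapi < dapi_high`` selects the DNA-content
    window. With ``include_g2m`` the gate additionally admits the G2/M window
    at twice the G0/G1 DAPI range, so cycling tumor nuclei are not counted as
    a separate (aneuploid-looking) population.
    """

    marker_threshold: float
    dapi_low: float
    dapi_high: float
    marker_positive: bool = True
    include_g2m: bool = False

    def __post_init__(self):
        if not np.isfinite(self.marker_threshold):
            raise ValueError("marker threshold must be finite")
        if not self.dapi_low < self.dapi_high:
            raise ValueError("gate requires dapi_low < dapi_high")

    def mask(self, events: pd.DataFrame) -> np.ndarray:
        marker = events["marker"].to_numpy(dtype=float)
        dapi = events["dapi"].to_numpy(dtype=float)
        if self.marker_positive:
            m = marker > self.marker_threshold
        else:
            m = marker <= self.marker_threshold
        window = (dapi >= self.dapi_low) & (dapi < self.dapi_high)
        if self.include_g2m:
            window |= (dapi >= 2 * self.dapi_low) & (dapi < 2 * self.dapi_high)
        return m & window


@dataclass
class SortedPopulation:
    """One flow-sorted population of a biopsy, as carried through the pipeline."""

    population_id: str
    patient_id: str
    biopsy_id: str
    site: str                    # "primary" | "metastasis" | "normal"
    marker_positive: bool
    ploidy: float                # DNA content, diploid = 2; reported to 1 decimal
    purity_presort: float        # in [0, 1]
    n_events: int = 0
    purity_postsort: float = float("nan")

    def __post_init__(self):
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if not 0.0 <= self.purity_presort <= 1.0:
            raise ValueError("purity must lie in [0, 1]")


def estimate_ploidy(tumor_dapi, reference_dapi) -> float:
    """Ploidy N = 2 x geomean(tumor DAPI) / geomean(diploid-reference DAPI).

    Both arrays must be non-empty and strictly positive (the geometric mean is
    undefined otherwise). The estimate is scale-invariant: multiplying every
    intensity by a common gain leaves it unchanged.
    """
    t = np.asarray(tumor_dapi, dtype=float)
    r = np.asarray(reference_dapi, dtype=float)
    if t.size == 0 or r.size == 0:
        raise ValueError("ploidy estimation needs non-empty tumor and reference samples")
    if (t <= 0).any() or (r <= 0).any():
        raise ValueError("DAPI intensities must be strictly positive")
    return 2.0 * float(gmean(t)) / float(gmean(r))


def dna_index_to_ploidy(dna_index: float) -> float:
    """Convert a DNA index (diploid = 1.0) to ploidy N (diploid = 2)."""
    if dna_index <= 0:
        raise ValueError("DNA index must be positive")
    return 2.0 * dna_index


def presort_purity(events: pd.DataFrame, tumor_gate: GateSpec, normal_gate: GateSpec) -> float:
    """Pre-sort tumor purity from gated event fractions.

    purity = (# events in tumor gate) / (# in tumor gate + # in normal gate).
    Events outside both gates (debris, other populations) are excluded from
    the denominator. The two gates must not overlap.
    """
    _check_disjoint(tumor_gate, normal_gate)
    n_t = int(tumor_gate.mask(events).sum())
    n_n = int(normal_gate.mask(events).sum())
    if n_t + n_n == 0:
        raise ValueError("no events fall inside either gate")
    return n_t / (n_t + n_n)


def _check_disjoint(a: GateSpec, b: GateSpec) -> None:
    if a.marker_positive != b.marker_positive:
        return
    def windows(g: GateSpec):
        w = [(g.dapi_low, g.dapi_high)]
        if g.include_g2m:
            w.append((2 * g.dapi_low, 2 * g.dapi_high))
        return w
    for lo1, hi1 in windows(a):
        for lo2, hi2 in windows(b):
            if lo1 < hi2 and lo2 < hi1:
                raise ValueError("tumor and normal gates overlap in (marker, DAPI) space")


@dataclass
class PuritySummary:
    mean_pct: int
    min_pct: int
    max_pct: int

    def __str__(self) -> str:
        return f"{self.mean_pct}% (range {self.min_pct}-{self.max_pct}%)"


def _as_percent(values) -> np.ndarray:
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("purity summary needs at least one population")
    if (v < 0).any():
        raise ValueError("purities must be non-negative")
    if (v <= 1.0).all():  # fractions
        v = v * 100.0
    return v

def summarize_purity(purities) -> PuritySummary:
    """Arithmetic mean (rounded to the nearest integer percent) and min-max
    range of per-population purities. Accepts fractions in [0,1] or percents."""
    v = _as_percent(purities)
    return PuritySummary(
        mean_pct=int(np.rint(v.mean())),
        min_pct=int(np.rint(v.min())),
        max_pct=int(np.rint(v.max())),
    )


def summarize_purity_table(table: pd.DataFrame,
                           pre_col: str = "purity_presort",
                           post_col: str = "purity_postsort") -> dict:
    """Pre- and post-sort purity summaries from a per-population table."""
    return {"presort": summarize_purity(table[pre_col]),
            "postsort": summarize_purity(table[post_col])}


# ---------------------------------------------------------------------------
# Automatic gate placement
# ---------------------------------------------------------------------------

def _dapi_peaks(dapi: np.ndarray, min_rel_height: float = 0.12) -> list[float]:
    """Modes of the kernel-smoothed DAPI histogram, largest peaks first
    by position. Peaks below `min_rel_height` of the maximum are ignored."""
    if dapi.size < 10:
        return [float(np.median(dapi))]
    kde = gaussian_kde(dapi)
    grid = np.linspace(dapi.min(), dapi.max(), 512)
    dens = kde(grid)
    peaks = []
    for i in range(1, len(grid) - 1):
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]:
            peaks.append((grid[i], dens[i]))
    if not peaks:
        return [float(grid[np.argmax(dens)])]
    top = max(d for _, d in peaks)
    return sorted(g for g, d in peaks if d >= min_rel_height * top)


def auto_gates(events: pd.DataFrame, rel_width: float = 0.18,
               include_g2m: bool = True) -> dict:
    """Place rectangular gates automatically.

    The marker threshold is Otsu's threshold on log-intensity; the normal gate
    sits on the G0/G1 DAPI peak of the marker-negative events, and one tumor
    gate is placed per detected DAPI peak of the marker-positive events.
    Peaks within 10% of twice a lower peak are treated as that peak's G2/M
    shoulder rather than a separate population. Returns
    ``{"threshold", "normal": GateSpec, "tumor": [GateSpec, ...]}``.
    """
    from skimage.filters import threshold_otsu

    marker = events["marker"].to_numpy(dtype=float)
    dapi = events["dapi"].to_numpy(dtype=float)
    if (marker <= 0).any():
        raise ValueError("marker intensities must be positive for log-Otsu thresholding")
    thr = float(np.exp(threshold_otsu(np.log(marker))))

    neg = dapi[marker <= thr]
    pos = dapi[marker > thr]
    if neg.size == 0 or pos.size == 0:
        raise ValueError("Otsu threshold left one marker class empty; gates cannot be placed")

    normal_peak = _dapi_peaks(neg)[0]
    normal_gate = GateSpec(thr, normal_peak * (1 - rel_width), normal_peak * (1 + rel_width),
                           marker_positive=False, include_g2m=False)

    tumor_gates = []
    kept: list[float] = []
    for p in _dapi_peaks(pos):
        if any(abs(p - 2 * q) / (2 * q) < 0.10 for q in kept):
            continue  # G2/M shoulder of an already-gated population
        kept.append(p)
        tumor_gates.append(GateSpec(thr, p * (1 - rel_width), p * (1 + rel_width),
                                    marker_positive=True, include_g2m=include_g2m))
    return {"threshold": thr, "normal": normal_gate, "tumor": tumor_gates}


def analyze_events(events: pd.DataFrame, patient_id: str = "P", biopsy_id: str = "B",
                   site: str = "primary", rel_width: float = 0.18) -> list[SortedPopulation]:
    """Full FACS analysis of one biopsy's event table.

    Auto-places gates, then for each detected tumor population estimates
    ploidy (geometric-mean ratio against the marker-negative diploid gate,
    G0/G1 windows only) and pre-sort purity. Returns one SortedPopulation per
    tumor gate, ordered by ploidy.
    """
    gates = auto_gates(events, rel_width=rel_width)
    normal_g01 = GateSpec(gates["threshold"], gates["normal"].dapi_low,
                          gates["normal"].dapi_high, marker_positive=False)
    ref = events.loc[normal_g01.mask(events), "dapi"].to_numpy()
    pops = []
    for i, tg in enumerate(gates["tumor"], start=1):
        g01 = GateSpec(tg.marker_threshold, tg.dapi_low, tg.dapi_high, marker_positive=True)
        tum = events.loc[g01.mask(events), "dapi"].to_numpy()
        if tum.size == 0:
            continue
        ploidy = round(estimate_ploidy(tum, ref), 1)
        purity = presort_purity(events, tg, gates["normal"])
        pops.append(SortedPopulation(
            population_id=f"{biopsy_id}T{i}", patient_id=patient_id, biopsy_id=biopsy_id,
            site=site, marker_positive=True, ploidy=ploidy,
            purity_presort=purity, n_events=int(tg.mask(events).sum()),
        ))
    return sorted(pops, key=lambda p: p.ploidy)
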
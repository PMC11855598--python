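"""Genome coordinate constants shared across modules.

All coordinates inside the package are 0-based half-open; conversion to
1-based happens only at the VCF boundary.
"""

from __future__ import annotations

# GRCh38 autosome lengths, rounded to the nearest Mb. Used as the default
# genome definition for simulation and CNV binning; a real analysis can pass
# its own chrom->length mapping anywhere a `genome` argument is accepted.
AUTOSOME_MB = {
    "chr1": 249, "chr2": 242, "chr3": 198, "chr4": 190, "chr5": 182,
    "chr6": 171, "chr7": 159, "chr8": 145, "chr9": 138, "chr10": 134,
    "chr11": 135, "chr12": 133, "chr13": 114, "chr14": 107, "chr15": 102,
    "chr16": 90, "chr17": 83, "chr18": 80, "chr19": 59, "chr20": 64,
    "chr21": 47, "chr22": 51,
}

DEFAULT_GENOME = {c: mb * 1_000_000 for c, mb in AUTOSOME_MB.items()}


def genome_order(genome: dict[str, int] | None = None) -> list[str]:
    """Chromosome names in their canonical order."""
    g = DEFAULT_GENOME if genome is None else genome
    return list(g.keys())
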
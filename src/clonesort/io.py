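"""Readers and writers for the pipeline's file formats.

Tabular formats are plain TSV/CSV via pandas. Variant tables round-trip
through either a MAF-like TSV (the wide in-memory convention, 0-based
positions) or a multi-sample VCF (1-based positions, AD/DP per population
sample; read through cyvcf2). Clone trees and seeding assignments are JSON;
parsimony and clone trees are also emitted as Newick.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .variants import VARIANT_KEY

_FIXED = ["chrom", "pos", "ref", "alt", "gene", "effect", "context"]


# --- variant tables --------------------------------------------------------

def write_maf_tsv(variants: pd.DataFrame, path) -> None:
    variants.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def read_maf_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df.index = pd.MultiIndex.from_frame(df[VARIANT_KEY])
    return df


def write_vcf(variants: pd.DataFrame, populations, path) -> None:
    """Write the wide variant table as a minimal multi-sample VCF 4.2.

    One sample column per sorted population with AD (ref,alt) and DP;
    gene/effect/context ride along in INFO. Positions convert 0-based ->
    1-based at this boundary.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Effect class">',
        '##INFO=<ID=CTX,Number=1,Type=String,Description="SBS96 trinucleotide channel">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(populations),
    ]
    for _, r in variants.iterrows():
        info = f"GENE={r['gene']};EFFECT={r['effect']}"
        if isinstance(r.get("context"), str):
            ctx = r["context"].replace(">", "-")  # '>' is awkward in INFO values
            info += f";CTX={ctx}"
        fields = [str(r["chrom"]), str(int(r["pos"]) + 1), ".", r["ref"], r["alt"],
                  ".", "PASS", info, "AD:DP"]
        for p in populations:
            alt = int(r[f"alt_{p}"])
            dp = int(r[f"dp_{p}"])
            fields.append(f"{dp - alt},{alt}:{dp}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a multi-sample VCF (as written by :func:`write_vcf` or any VCF
    with per-sample AD) into the wide variant-table convention."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    pops = list(vcf.samples)
    rows = []
    for rec in vcf:
        ctx = rec.INFO.get("CTX")
        row = {
            "chrom": rec.CHROM, "pos": rec.POS - 1, "ref": rec.REF, "alt": rec.ALT[0],
            "gene": rec.INFO.get("GENE", ""), "effect": rec.INFO.get("EFFECT", "other"),
            "context": ctx.replace("-", ">") if ctx else None,
        }
        ad = rec.format("AD")
        dp = rec.format("DP")
        for j, p in enumerate(pops):
            row[f"alt_{p}"] = int(ad[j][1])
            row[f"dp_{p}"] = int(dp[j][0]) if dp is not None else int(ad[j].sum())
        rows.append(row)
    df = pd.DataFrame(rows)
    df.index = pd.MultiIndex.from_frame(df[VARIANT_KEY])
    return df


# --- simple tables ---------------------------------------------------------

def write_segments_tsv(segments: pd.DataFrame, path) -> None:
    segments.to_csv(path, sep="\t", index=False)


def read_segments_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_facs_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_facs_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_driver_list(path) -> list[str]:
    """One gene symbol per line; blank lines and #-comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


# --- JSON ------------------------------------------------------------------

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(x):
    try:
        import numpy as np
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(x, (set, frozenset, tuple)):
        return sorted(x) if isinstance(x, (set, frozenset)) else list(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(outdir, files, extra=None) -> None:
    outdir = Path(outdir)
    manifest = {"files": {name: sha256_of(outdir / name) for name in sorted(files)}}
    if extra:
        manifest.update(extra)
    write_json(manifest, outdir / "manifest.json")
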
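"""End-to-end orchestration: simulate -> FACS -> filter -> CCF -> clusters ->
clone tree -> seeding -> parsimony -> signatures -> CNV -> report.

The pipeline is deterministic for a fixed seed: every stochastic stage draws
from generators derived from the run seed, and `report.json` is written with
sorted keys and rounded floats so reruns are byte-identical. Per-stage wall
times go to `run.log` (deliberately outside the hashed manifest).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ccf as ccf_mod
from . import cnv as cnv_mod
from . import facs as facs_mod
from . import io as io_mod
from . import phylo as phylo_mod
from . import signatures as sig_mod
from . import sim as sim_mod
from .clones import (CCFMixtureModel, build_clone_tree, ccf_trace,
                     filter_clusters, infer_seeding)
from .variants import (FilterConfig, annotate_drivers, apply_filters,
                       presence_matrix, shared_private_summary, tmb)

#: Melanoma driver genes (Bailey-style selection) used when no list is given.
DEFAULT_DRIVER_GENES = (
    "BRAF", "NRAS", "NF1", "KIT", "TP53", "CDKN2A", "PTEN", "PPP6C", "KMT2D",
    "COL5A1", "CTNNB1", "MECOM", "RAC1", "ARID2", "MAP2K1", "IDH1", "HRAS",
)

PRESETS = {
    "patient1": sim_mod.patient1_config,
    "patient2": sim_mod.patient2_config,
    "patient3": sim_mod.patient3_config,
}


@dataclass
class PipelineConfig:
    preset: str = "patient1"
    seed: int = 17
    outdir: str = "clonesort_out"
    scale: float = 1.0
    depth_mean: float = 150.0
    k_max: int = 8
    n_init: int = 20
    min_cluster_size: int = 5
    tmb_mb: float = 35.7
    cnv_bin_size: int = 1_000_000
    trunk_mode: str = "strict"
    driver_genes: tuple = DEFAULT_DRIVER_GENES
    filter_config: FilterConfig = field(default_factory=FilterConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        filt = FilterConfig(**raw.pop("filter", {}))
        return cls(filter_config=filt, **raw)


def _round_floats(obj, ndigits=4):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-patient pipeline; returns the report dict and
    writes all per-patient outputs plus a hashed manifest under `outdir`."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines, t0 = [], time.perf_counter()

    def stage(name):
        log_lines.append(f"{name}\t{time.perf_counter() - t0:.2f}s")

    if config.preset not in PRESETS:
        raise ValueError(f"unknown preset {config.preset!r}; choose from {sorted(PRESETS)}")
    sim_cfg = PRESETS[config.preset](seed=config.seed, scale=config.scale,
                                     depth_mean=config.depth_mean)
    sim = sim_mod.simulate_patient(sim_cfg)
    pops = sim_cfg.population_names()
    stage("simulate")

    # --- FACS: ploidy + pre-sort purity from event tables ------------------
    facs_rows = []
    for spec in sim_cfg.populations:
        events = sim.facs[spec.biopsy]
        detected = facs_mod.analyze_events(events, patient_id=sim_cfg.patient_id,
                                           biopsy_id=spec.biopsy, site=spec.site)
        match = min(detected, key=lambda d: abs(d.ploidy - spec.ploidy)) if detected else None
        facs_rows.append({
            "population": spec.name, "biopsy": spec.biopsy, "site": spec.site,
            "ploidy_true": spec.ploidy,
            "ploidy_facs": match.ploidy if match else float("nan"),
            "purity_presort_true": spec.purity_presort,
            "purity_presort_facs": round(match.purity_presort, 3) if match else float("nan"),
            "purity_postsort_true": spec.purity_postsort,
        })
    populations_tbl = pd.DataFrame(facs_rows)
    stage("facs")

    # --- variant filtering --------------------------------------------------
    retained, tally = apply_filters(sim.variants, config.filter_config, pops)
    stage("filter")
    if len(retained) == 0:
        import warnings

        warnings.warn("no variants survived filtering; emitting a skeleton report")
        report = {"patient": sim_cfg.patient_id, "seed": config.seed,
                  "preset": config.preset, "filter_tally": tally,
                  "warnings": ["no variants survived filtering"], "clusters": None,
                  "seeding": {}, "seeding_truth": sim.truth.seeding}
        populations_tbl.to_csv(outdir / "populations.tsv", sep="\t", index=False)
        io_mod.write_json(_round_floats(report), outdir / "report.json")
        io_mod.write_manifest(outdir, ["populations.tsv", "report.json"],
                              extra={"seed": config.seed})
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        return report

    # --- post-sort purity + CCF --------------------------------------------
    lookup = sim_mod.cn_lookup_from_profiles(sim.cn_profiles)
    pres = presence_matrix(retained, pops)
    truncal = retained.loc[pres.sum(axis=1) == len(pops)]
    purity_est = {}
    for pop in pops:
        alt = truncal[f"alt_{pop}"].to_numpy(float)
        dp = np.maximum(truncal[f"dp_{pop}"].to_numpy(float), 1.0)
        cn_t = np.array([lookup(pop, c, p)[0] for c, p in
                         zip(truncal["chrom"], truncal["pos"])], dtype=float)
        het = cn_t > 0
        purity_est[pop] = ccf_mod.estimate_purity_from_truncal(
            (alt / dp)[het], cn_tumor=cn_t[het])
    populations_tbl["purity_postsort_est"] = [round(purity_est[p], 3) for p in pops]
    ccf_tbl = ccf_mod.ccf_table(retained, pops, purity_est, lookup)
    stage("ccf")

    # --- clustering, clone tree, seeding ------------------------------------
    model = CCFMixtureModel.from_variants(retained, pops, purity_est, lookup)
    results = model.fit(k_max=config.k_max, n_init=config.n_init, seed=config.seed)
    clusters, unassigned = filter_clusters(results.clusters(), config.min_cluster_size)
    tree = build_clone_tree(clusters)
    profiles = [cnv_mod.CNSegmentProfile(p, sim.cn_profiles[p], sim.truth.ploidy[p])
                for p in pops]
    corr, corr_p = cnv_mod.correlation_matrix(profiles, bin_size=config.cnv_bin_size)
    sites = {p.name: p.site for p in sim_cfg.populations}
    seeding = infer_seeding(clusters, sites, cnv_correlation=corr)
    trace = ccf_trace(clusters, pops)
    stage("clones")

    # --- parsimony -----------------------------------------------------------
    parsimony = phylo_mod.max_parsimony_tree(pres)
    trunk = phylo_mod.classify_trunk(pres, mode=config.trunk_mode)
    stage("phylo")

    # --- signatures ----------------------------------------------------------
    reference = sig_mod.toy_reference()
    exposures = {}
    for pop in pops:
        ctx = retained.loc[pres[pop] == 1, "context"]
        spectrum = sig_mod.spectrum_from_contexts(ctx)
        if spectrum.sum() == 0:
            continue
        exp = sig_mod.group_others(sig_mod.refit(spectrum, reference))
        exposures[pop] = {k: round(float(v), 4) for k, v in exp.grouped.items()}
    stage("signatures")

    # --- CNV -----------------------------------------------------------------
    categories = pd.concat(
        [call.assign(population=prof.population_id)
         for prof in profiles
         for call in [cnv_mod.call_categories(prof)]],
        ignore_index=True)
    homdels = {prof.population_id:
               cnv_mod.find_homozygous_deletions(prof, sim_mod.MELANOMA_GENE_INTERVALS)
               for prof in profiles}
    stage("cnv")

    # --- driver matrix / summaries ------------------------------------------
    clon = ccf_tbl.pivot(index="mutation_id", columns="population", values="label")
    clon.index = pd.MultiIndex.from_tuples(clon.index)
    _, driver_matrix, driver_summary = annotate_drivers(
        retained, config.driver_genes, clonality=clon)
    sp = shared_private_summary(retained, pops)
    tmb_by_pop = {p: tmb(retained, p, config.tmb_mb) for p in pops}
    stage("summaries")

    # --- outputs -------------------------------------------------------------
    files = {}

    def emit(name, writer, *args):
        writer(*args, outdir / name)
        files[name] = True

    emit("populations.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), populations_tbl)
    emit("filtered.maf.tsv", io_mod.write_maf_tsv, retained.drop(
        columns=[c for c in retained.columns if c.startswith("pass_")]))
    emit("ccf.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), ccf_tbl)
    emit("clusters.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), trace)
    emit("clonetree.json", io_mod.write_json, tree.to_dict())
    Path(outdir / "clonetree.nwk").write_text(tree.to_newick() + "\n")
    files["clonetree.nwk"] = True
    emit("seeding.json", io_mod.write_json, seeding.to_dict())
    Path(outdir / "parsimony.nwk").write_text(parsimony.newick + "\n")
    files["parsimony.nwk"] = True
    emit("signatures.tsv", lambda d, p: pd.DataFrame(d).fillna(0.0).to_csv(p, sep="\t"),
         exposures)
    emit("cnv_categories.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), categories)
    emit("correlation.tsv", lambda df, p: df.to_csv(p, sep="\t"), corr.round(4))

    report = {
        "patient": sim_cfg.patient_id,
        "seed": config.seed,
        "preset": config.preset,
        "n_mutations_simulated": int(len(sim.variants)),
        "filter_tally": tally,
        "purity": {
            "presort": vars(facs_mod.summarize_purity(populations_tbl["purity_presort_facs"])),
            "postsort_est": vars(facs_mod.summarize_purity(
                populations_tbl["purity_postsort_est"])),
        },
        "tmb": tmb_by_pop,
        "shared_private": sp,
        "drivers": driver_summary,
        "clusters": {
            "k_selected": results.n_clusters,
            "n_kept": len(clusters),
            "n_unassigned_mutations": len(unassigned),
            "sizes": sorted((c.size for c in clusters), reverse=True),
        },
        "seeding": seeding.assignments,
        "seeding_truth": sim.truth.seeding,
        "parsimony_score": parsimony.score,
        "trunk_classification": trunk.value_counts().to_dict(),
        "signatures": exposures,
        "homozygous_deletions": homdels,
        "cnv_correlation": {f"{a}|{b}": round(float(corr.loc[a, b]), 4)
                            for i, a in enumerate(pops) for b in pops[i + 1:]},
    }
    io_mod.write_json(_round_floats(report), outdir / "report.json")
    files["report.json"] = True
    io_mod.write_manifest(outdir, list(files), extra={"seed": config.seed})
    stage("report")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    if driver_matrix is not None and len(driver_matrix):
        driver_matrix.to_csv(outdir / "driver_matrix.tsv", sep="\t")
    return report
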
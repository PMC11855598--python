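# clonesort

Clonal-evolution analysis for **flow-sorted tumor populations**.

Melanoma biopsies are often polygenomic: a single piece of tissue can hold
two or more genomically distinct tumor cell populations, distinguishable by
DNA content (ploidy). Multiparameter ploidy sorting isolates those
populations by FACS — DAPI for DNA content, SOX10/S100 as melanoma lineage
markers — and each sorted population is exome-sequenced as its own
high-purity sample. `clonesort` implements the downstream analysis of that
design:

- **facs** — ploidy from geometric-mean DAPI ratios
  (`N = 2·gmean(tumor)/gmean(diploid)`), DNA-index conversion, automatic
  rectangular gating, pre-sort purity from gate event fractions;
- **variants** — the somatic filtering cascade (VAF ≥ 1%, ≥ 3 alt reads,
  relaxed to 2 with cross-population support, panel-of-normals exclusion),
  driver annotation, TMB, shared/private summaries;
- **ccf** — closed-form cancer cell fractions
  `CCF = f·(p·CN_t + (1−p)·CN_n)/(p·m)` with Jeffreys intervals and
  clonal/subclonal calls (P(CCF ≥ 0.9) > 0.5 or CI lower bound > 0.9);
- **clones** — multi-sample CCF clustering via a seeded finite binomial
  mixture (`CCFMixtureModel(...).fit()` → `CCFMixtureResults`), BIC model
  selection, ≥ 5-mutation cluster filter, containment-based clone trees, and
  metastasis-seeding inference with CNV-correlation tie-breaking;
- **phylo** — exhaustive maximum-parsimony trees (Fitch scoring, germline
  outgroup) and trunk/branch/private classification;
- **signatures** — NNLS refitting of 96-channel mutation spectra against a
  COSMIC-format reference, with < 5% contributions pooled as "others";
- **cnv** — copy-number categories relative to ploidy, binned Pearson
  profile correlation, homozygous-deletion reporting;
- **sim** — a generative simulator of whole patients (clone trees, sorted
  populations, FACS events, binomial read counts, CN profiles, signature
  mixtures) with complete ground truth, so the entire pipeline runs and is
  tested without any sequencing data.

## Worked example

Simulate a polygenomic patient — two primary-site tumor populations
(ploidies 1.7 and 2.7) plus a skin and a lymph-node metastasis, each seeded
by a different primary population — and run the full pipeline:

```bash
clonesort demo --seed 17 --outdir demo_out
# seeding recovered correctly: True
# report written to demo_out/report.json
```

Key numbers from `demo_out/report.json` (quarter-scale simulation,
606 retained mutations):

```
clusters        k_selected 6, sizes [378, 74, 56, 50, 39, 9]
seeding         {"1MT1": "1PST2", "1MT2": "1PST1"}   (matches truth)
shared_private  shared by all 378/606 = 62.4%, partially shared 37.6%
purity          post-sort estimate mean 92% (range 88–96%)
tmb             15.9 (1PST1) … 13.8 mutations/Mb
cnv_correlation 1PST1|1MT2 R = 0.92, 1PST2|1MT1 R = 0.76 (lineage pairs)
signatures      UV-dominated in all four populations (≈ 0.76)
```

The clustering recovered the six simulated clusters; the seeding map —
lymph-node metastasis from the low-ploidy primary population, skin
metastasis from the high-ploidy one — follows from the clusters each
metastasis shares *exclusively* with one primary, corroborated by the
copy-number correlation structure. Other entry points:
`clonesort simulate`, `facs`, `filter`, `run --preset patient2|patient3`,
and the library API (`clonesort.CCFMixtureModel.from_variants(...)`).

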
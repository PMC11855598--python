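# Methods

`clonesort` reconstructs the clonal evolution of melanomas profiled by
multiparameter ploidy sorting: nuclei from a biopsy are flow-sorted on DNA
content (DAPI) and a melanoma lineage marker (SOX10 or S100), and each sorted
tumor population is exome-sequenced as its own sample. The package covers the
dry half of that design — from per-population read counts, copy-number
segments, and FACS event tables to mutation clusters, clone trees, seeding
assignments, parsimony phylogenies, and signature exposures — plus a
generative simulator that stands in for patient data, which cannot be
redistributed.

## FACS quantities

Ploidy of a sorted population is `N = 2 * gmean(DAPI_tumor) / gmean(DAPI_normal)`,
the geometric-mean ratio of tumor to marker-negative diploid events; a DNA
index `I` (diploid = 1) converts as `N = 2I`. The estimator is scale-invariant,
so detector gain cancels. Pre-sort purity is the fraction of events in the
tumor analysis gate among events in either the tumor or the diploid normal
gate; events in neither gate (debris, doublets) are excluded from the
denominator. Gates are rectangles in (marker, DAPI) space placed
automatically — Otsu's threshold on log marker intensity, kernel-density
peaks on DAPI — with the tumor gate optionally extended by a window at twice
the G0/G1 peak so cycling (G2/M) tumor nuclei are retained. Automatic
placement trades the flexibility of manual gating for reproducibility; it
assumes reasonably separated populations and will merge tumor peaks closer
than ~10% of each other in DNA content (a peak near twice a smaller peak is
interpreted as its G2/M shoulder, which is the right call for G0/G1+G2/M
data and the wrong one for a true 2x-ploidy coincidence).

## Variant filtering

A variant is kept in population *p* when `VAF_p >= 1%` and it has at least 3
supporting reads; the read cut-off relaxes to 2 when the variant
independently passes the primary rule in another sorted population of the
same patient (cross-population evidence). Variants observed in two or more
samples of a panel of normals are removed everywhere. The cut-off counts
alt-supporting reads by default (`count_mode="alt"`); reading the rule as
total depth is available as `count_mode="total"`. The discard tally
attributes each lost variant to the first matching rule (panel, VAF floor,
read floor) so tallies always partition the input. The cascade is
idempotent.

Tumor mutational burden divides retained coding (synonymous +
non-synonymous) mutations by the callable exome size, default 35.7 Mb — a
typical value for a V6-class exome capture; the true denominator depends on
the capture kit and coverage and should be supplied when known.

## CCF estimation

For a mutation with VAF *f* in a population of purity *p*, local tumor copy
number `CN_t`, normal copy number `CN_n = 2`, and multiplicity *m*:

    CCF = f * (p*CN_t + (1-p)*CN_n) / (p * m)

Multiplicity is the rounded mutated-copy count
`clamp(round(f*(p*CN_t+(1-p)*CN_n)/p), 1, CN_t)`. Note that only the product
`m*CCF` is identified from a single sample; the rounding resolves it exactly
for clonal and near-clonal mutations and leaves half-integer products (e.g.
m=3 at CCF 0.5) ambiguous by construction. Raw CCFs are clipped to [0, 1.2]
for diagnostics and capped at 1 for classification and clustering.

Uncertainty comes from a Jeffreys Beta(alt+1/2, ref+1/2) posterior on the
VAF pushed through the (linear, monotone) CCF map — a closed-form choice
with good behaviour at low read counts. A mutation is **clonal** when its
posterior probability of CCF >= 0.9 exceeds 50%, or the lower bound of its
95% CCF interval exceeds 0.9; otherwise subclonal. The probability rule and
the plain point-estimate cut-off (CCF >= 0.9) agree except near the
boundary; the probabilistic rule is the default.

Post-sort purity, when not supplied, is estimated by inverting the expected
truncal-heterozygous VAF (`p = f*CN_n / (1 + f*CN_n - f*CN_t)`) and taking
the median over truncal sites — robust to the multiplicity >= 2 minority but
not a replacement for an allele-specific CN fit.

## CCF clustering

Mutations are clustered across all populations of a patient jointly with a
finite binomial mixture: cluster *k* has a CCF vector `c_k` over populations,
and `alt_ip ~ Binomial(depth_ip, a_ip * c_kp)` with `a_ip` the deterministic
CCF-to-VAF conversion at that locus. EM with k-means++-style seeding on
naive per-mutation CCF vectors, 20 restarts, and exact coordinate-wise
M-steps (the expected complete-data log-likelihood is strictly concave in
each `c_kp`; a safeguarded Newton step plus an accept-only-if-better check
makes the observed log-likelihood provably non-decreasing). K is chosen by
BIC over 1..K_max (default 8). This replaces Dirichlet-process subclonal
samplers with a deterministic, seconds-scale fit; it does not produce a
posterior over trees, and it assumes a shared CCF vector per cluster (no
within-cluster CCF dispersion beyond binomial noise).

Clusters with fewer than 5 mutations are discarded; their mutations are
reported unassigned rather than forced into neighbours.

## Clone tree and seeding

The clone tree roots at the truncal cluster (CCF >= 0.9 everywhere). Each
cluster attaches to its *minimum containing superset*: the cluster with the
smallest total CCF that dominates it in every population within an absolute
tolerance of 0.05. A chain forms only when containment holds in all
populations; otherwise siblings attach to the common ancestor. Violations of
the sum rule (children's CCFs exceeding the parent's by more than the
tolerance in some population) and orphan clusters are flagged in the output,
not silently repaired.

Each metastasis is assigned the primary population with which it exclusively
shares the most clusters (cluster present means CCF > 0.1 in both, and <= 0.1
in every other primary). Ties and zero-evidence cases fall back to the
highest Pearson correlation between binned copy-number profiles; a
metastasis with neither signal is reported unresolved. The presence
threshold and containment tolerance are package choices — the underlying
study design does not pin them — and both are configurable.

## Maximum parsimony

Presence/absence matrices over populations (plus an all-zero germline
outgroup) are scored with Fitch's algorithm over an exhaustive enumeration
of rooted topologies (one per unrooted topology, rooted on the outgroup
pendant edge); practical up to 10 populations, which covers sorted-population
designs with room to spare. Ties are reported in full, with the
lexicographically smallest canonical Newick as the primary output. Branch
lengths are mutation counts from the top-down Fitch assignment (root forced
to germline state). Trunk/branch/private labels come in two conventions:
`strict` (trunk = present in all populations; default) and `biopsy`
(trunk = present in >= 2).

## Signature refitting

Spectra are tallied over the 96 pyrimidine-centred trinucleotide channels
and decomposed against a fixed signature reference by non-negative least
squares, normalised to fractions; contributions below 5% are pooled into
"others" for display. No sparsity penalty or pre-selection is applied — with
a fixed reference and exome-scale counts, plain NNLS is stable and exactly
reproducible. The bundled four-signature reference (UV-like, platinum-like,
alkylating-like, flat) is synthetic, built from deterministic channel rules
so tests need no external catalogue; any COSMIC-format TSV is accepted for
real analyses. Refits can be computed per population or per branch
(private-mutation sets); both entry points exist because either view is
legitimate depending on whether exposure is read as a property of a sample
or of a lineage segment.

## Copy number

Segment categories are integer-CN rules relative to rounded population
ploidy: total CN 0 is a homozygous deletion; below ploidy, loss; at ploidy,
neutral; above by less than 3, gain; by 3 or more, amplification. The
amplification offset mirrors common post-segmentation practice and is
configurable. Profile similarity is Pearson correlation of log ratios
rasterised to 1 Mb bins (bins assigned by midpoint), computed on bins
covered in both profiles; constant profiles return r = 0 with p = 1, since a
flat profile carries no correlation signal. Homozygous-deletion reporting
intersects CN-0 segments with gene intervals under half-open semantics.

## The simulator

`sim` generates whole patients with ground truth: a rooted tree of mutation
clusters with per-population CCFs (containment enforced at config
validation), binomial read sampling (`depth ~ Poisson(mean 150)`,
`alt ~ Binomial(depth, m*CCF*purity / (purity*CN_t + (1-purity)*2))`),
signature-mixture multinomial contexts, per-population segment profiles, and
per-biopsy FACS event tables with log-normal DAPI (geometric mean exactly
ploidy-proportional; CV 0.05 default) and a configurable G2/M fraction at
twice the G0/G1 signal. All randomness flows from one integer seed;
identical seeds give byte-identical outputs.

Three presets mirror the archetypes of the sorted-population design:
`patient1` is a polygenomic primary (populations at ploidy 1.7 and 2.7 in
one biopsy, post-sort purities 0.88–0.95) with six clusters
(1513/298/156/199/34/227 mutations) forming two lineages that seed two
different metastases; `patient2` is a near-diploid pair sharing 995 of 1072
mutations; `patient3` carries a chemotherapy-exposed metastasis (813 of 1164
mutations private, platinum/alkylating mixture) and primary-only homozygous
deletions at 9p21, 11q13, and 11p15. Cluster sizes, purities, ploidies and
CCF patterns are fixed at the cohort's reported values; one cluster size per
patient is reconciled so patient totals match the reported totals. The
`scale` knob shrinks cluster sizes proportionally (topology, CCFs, depths
and purities unchanged); repeated-simulation studies in the test suite and
acceptance script run at quarter scale (~600 mutations/patient) to keep a
20-replicate study in the minutes range, with single-patient checks at full
scale.

What the simulator does **not** model — and therefore what passing recovery
tests cannot certify about real data: sequencing error and mapping artifacts
(absent mutations yield exactly zero alt reads), subclonal copy number
within a sorted population, sorting cross-contamination between populations,
doublets, FFPE damage, and germline leakage beyond the panel filter. Recovery
results on simulated patients are best read as *internal consistency* of the
estimator chain under the stated generative model.

## Numerical choices and degenerate inputs

- EM: expected VAFs clipped to [1e-9, 1-1e-9]; empty clusters keep a floor
  weight of 1e-9/n; convergence at absolute log-likelihood change < 1e-3,
  max 150 iterations; Newton M-step capped at 15 iterations with elementwise
  fall-back to the previous value.
- Jeffreys intervals: the lower bound is forced to exactly 0 at alt = 0 and
  the upper to 1 at alt = depth.
- CCF conversions guard against depth 0 (treated as depth 1 with alt 0) and
  copy number 0 (expected VAF 0; such loci carry no CCF information).
- An empty post-filter variant table short-circuits the pipeline into a
  skeleton report with a warning instead of failing.
- Ploidy is reported to 1 decimal; purity summaries round to integer
  percent; report floats round to 4 decimals so reruns are byte-identical.

## Known limitations

Exhaustive parsimony only (no heuristic mode above 10 populations); no
mutation-timing or multi-tree posterior; the clonal-probability rule treats
populations independently (no joint multi-sample clonality call); CNV
correlation ignores allele-specific (minor-copy) information; FACS gating
assumes a detectable diploid marker-negative reference population in every
biopsy.
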
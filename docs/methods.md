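# Methods

This note records the models, parameter defaults, numerical choices and
known limitations of `lplpipe`. It is the package's own account of its
design; empirical claims below are limited to what the test suite and
`scripts/acceptance.py` themselves compute.

## Synthetic data model (`synthio`)

The generator emulates the study design the pipeline targets: a small
mouse cohort (3 control + 4 tumor spleens), an 11-sample human reference
cohort, a 58-sample multi-entity human validation cohort sharing a
sign-coherent signature with the mouse tumors, and 5′RACE repertoire
libraries from 5 control and 6 tumor animals that are clonal in the µ
heavy chain only.

**Expression.** Per-gene baselines are drawn once from N(8, 1.5²) (log2
scale, typical microarray range) and shared across samples; i.i.d. N(0,
noise_sd²) noise is added per cell. Planted clusters add a signed log2
shift in the designated class; a cluster may instead specify an explicit
class → shift map, which is what makes clusters with the same overall
direction distinguishable after per-gene standardization (a single shared
affected class collapses all same-direction genes onto one standardized
profile). Defaults are effect 2.0 log2 units and noise sd 0.5 — i.e. a
4-pooled-sd class separation, a deliberately strong "clean signal"
calibration — because the emulated arrays publish no effect-size or
variance figures. These defaults are used verbatim by the acceptance
script.

Features of real arrays the generator does *not* model: probe-level
intensities and normalization artifacts, gene–gene correlation beyond the
planted block structure, heteroscedasticity, batch effects. Passing tests
therefore demonstrate correctness of the algorithms under their own
assumptions, not robustness to real-array pathology.

**Cross-species cohorts.** Signature genes alternate up/down
deterministically; a Bernoulli(discordance_rate) subset has its human
sign flipped. Orthology is encoded by the symbol convention (mouse
title-case ↔ human upper-case). Only the designated positive human class
carries the signature, so arbitrarily many signature-silent entities can
be added to the validation cohort.

**Repertoire.** Each (sample, chain) has membrane and secreted libraries
drawn multinomially with `n_reads` reads. Background clone abundances
follow a geometric law with head probability 0.05 (one-parameter
rank-abundance decay); the clone *identities* are shared between the two
isoform libraries of a (sample, chain) but their abundance ranks are
permuted independently, so in polyclonal samples the dominant membrane
and secreted clones coincide only by chance. Clonal samples place
probability `dominant_freq` on a single clonotype shared by both isoform
libraries — the lymphoplasmacytic hallmark of one V(D)J rearrangement
expressed as both surface and secreted heavy chain. FASTQ emission is off
by default; when on, each read pair covers a 104-nt template
(8-nt barcode + 40-nt clone-specific leader + 36-nt junction + 20-nt
isoform primer) with 60-nt reads, i.e. a 16-nt overlap, and Q40 bases.
No somatic-hypermutation or sequencing-error model is included, so
read-level tests exercise bookkeeping (merging, demultiplexing,
aggregation), not error tolerance.

All randomness in a call flows from one integer seed through a single
generator; identical (arguments, seed) give byte-identical outputs.

## Differential expression (`diffexpr`)

The moderated statistic shrinks the pooled two-sample variance toward a
prior: s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), with the t reference on
d₀ + d_g df. When prior_df/prior_var are `auto`, (d₀, s₀²) are estimated
by the method of moments on log sample variances: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess of var(e) over
ψ′(d_g/2) is inverted through the trigamma function (Newton iteration) to
give d₀, and the mean of e gives s₀². This is the standard
empirical-Bayes recipe for expression arrays; a frozen fixture in the
test suite verifies agreement with the reference R implementation
(limma's `eBayes`) to ~1e-14 on both the hyperparameters and the
statistics. Non-positive excess variance means the observed variances are
under-dispersed relative to chi-square sampling noise; d₀ is then
infinite and every posterior variance equals s₀². An all-constant gene
with no prior has s̃ = 0 and is reported as stat 0, p 1 rather than
dividing by zero.

Selection applies three gates in order: |log2fc| ≥ log2(fc_threshold)
(default 2, i.e. two-fold), Benjamini–Hochberg adjusted p ≤ α (default
0.05; BH is the field default for expression screens), then a
heterogeneity filter keeping the ⌈q·k⌉ genes with lowest pooled
within-group sd among the k passing genes, ties broken by input gene
order. The default q = 0.47 mirrors the attrition of the workflow this
package re-implements, which retained 1515 of 3236 fold-change-passing
transcripts at the heterogeneity stage; whether that filter originally
acted before or after the fold-change gate is not documented, so the
order here (after) is a package decision and is configurable.

## Cluster aggregation (`aggclust`)

Gene profiles are standardized per gene before clustering (so clusters
encode response *shape*, not magnitude). k-means (squared-Euclidean,
k-means++ seeding, best of 10 restarts by inertia, default k_init = 40)
gives the initial partition; empty clusters are re-compacted. Greedy
merging always joins the pair of clusters closest in the plane of the
first min(2, k−1) principal components of the *current* column-centered
centroid matrix — the PCA is recomputed at every step because the mean
vectors evolve — with distance ties going to the lexicographically
smallest index pair. Merging stops at k = 2, below which a contingency
criterion is meaningless.

Each level is scored by std_chi2 = (χ² − df)/√(2·df) on the contingency
table of the current partition against a reference partition (empty rows
and columns removed; df = 0 defines the score as 0). The standardization
makes Pearson chi-square values comparable across df; the selected level
k\* maximizes |std_chi2|, ties going to the largest k.

Two reference modes are provided, and the choice matters:

- `hierarchical` (default): the reference is a Ward-linkage clustering of
  the same standardized profiles cut at the current k, so std_chi2
  measures concordance of the k-means/merge route with the hierarchical
  route. A structural property of this criterion is worth stating
  plainly: any *pure coarsening* (every merged cluster concordant with a
  reference cluster) has χ² = n(r−1) (Cramér V = 1), hence
  std_chi2 = (n−r+1)/√2, which increases as k falls. When both routes
  agree at every level at and below the true cluster number — the typical
  situation for well-separated clusters of similar size — the criterion
  is therefore maximized at k = 2, not at the true k. It peaks in the
  interior only when the two routes start disagreeing below the true k
  (e.g. under strongly unequal cluster sizes, where Ward's size-weighted
  merge cost and the unweighted centroid distance pick different pairs).
- `direction`: the reference is the fixed two-column up/down fold-change
  partition for a given contrast. The criterion then rewards
  direction-pure partitions, and over-merging is penalized exactly when
  the closest remaining pair has opposite directions. The planted-cluster
  recovery tests use this mode with a geometry in which the two nearest
  clusters respond in opposite directions, giving a large interior
  maximum at the true k.

The merge trace (step, pair, χ², std_chi2, k) is recorded and replayable;
re-running the trace from the initial assignment reproduces the final
partition exactly.

## Cross-species signature (`xspecies`)

Probesets collapse to genes by keeping the probeset with highest mean
expression (a common convention; the collapse rule is not dictated by the
gene/probeset counts it must reproduce). Ortholog pairing defaults to
case-insensitive symbol equality, unique per mouse gene, with an explicit
two-column map taking precedence when supplied. The coherent signature
keeps ortholog pairs selected in both species whose fold changes share a
sign; the shared sign is the recorded direction, so coherence holds by
construction and the up/down tallies are conserved through TSV
round-trips.

Branch coherency clusters the signature genes in each cohort
independently (Ward on standardized profiles, cut into exactly 2
branches, matching the up/down dichotomy), labels each branch by the sign
of its mean contrast (zero-mean branches fall back to the majority of
per-gene signs, ties labeled up, with a log line), and reports the
fraction of genes with equal labels in the two cohorts. With strong
planted effects this fraction recovers 1 − discordance_rate.

## LPS classifier (`wrightlps`)

Coefficients are plain two-sample pooled t statistics — deliberately not
the moderated statistic, to keep the classifier faithful to the linear
predictor score method it implements. Zero-variance genes get coefficient
0 with a warning. Class-conditional Gaussians are fitted to training
scores by sample mean and sd (ddof 1); posteriors use log-density
differences through a clipped logistic for numerical stability. The
thresholds p_hi = 0.9 / p_lo = 0.1 realize a "positive with ≥ 90%
probability" call with a symmetric negative call and an NA zone between.

The compact-predictor refinement is a package decision (the size of the
original predictor set is documented, its construction is not): candidates
are ranked by |a_j|, prefixes are scored by leave-one-out assignment
quality (+1 correct, 0 NA, −1 wrong), and the best prefix (ties → fewer
genes) is refitted on all samples. Leave-one-out refits are exact, not
approximated, so the procedure is quadratic in practice and intended for
candidate lists up to a few hundred genes.

## Clonality (`clonality`)

Read merging scans overlap lengths from the longest down to
`min_overlap` (default 10), accepts overlaps with mismatch density ≤ 0.25,
and among accepted overlaps keeps the lowest density (ties → longest);
disagreeing overlap bases resolve to the higher quality score (ties to
read 1). Demultiplexing matches the sample barcode exactly at the 5′ end
and the isoform primer with at most one mismatch at the 3′ end; synthetic
primers are generated with pairwise Hamming distance ≥ 5 so one mismatch
never makes assignment ambiguous. Unassigned reads are tallied and
dropped.

Clonotypes are keyed by (v_call, j_call, junction) when germline
annotations exist — germline alignment itself is consumed, never
computed — and by exact identity of the barcode/primer-trimmed merged
sequence otherwise. Frequencies are counts over the library total;
ordering ties break lexicographically by key so reports are
deterministic. The dominant membrane/secreted match compares full keys.

The rank-sum test uses pooled mid-ranks and enumerates all C(n+m, n)
group assignments exactly for n + m ≤ 12 (covering the 5-vs-6 design with
headroom while keeping enumeration ≤ 924 assignments); two-sided p is
min(1, 2·min(tail probabilities)). Larger samples use the normal
approximation with tie-corrected variance and a 0.5 continuity
correction, with a log line marking the switch.

## Problem sizes

Test and acceptance runs use deliberately desk-scale cohorts chosen as
the package's own defaults: 90–2000 genes, the 7/11/58-sample cohort
shapes above, 500–10 000 reads per library, 10–30 seed replicates.
The headline check (acceptance target) trains and validates the LPS
classifier on disjoint 58-sample cohorts with a 174-gene signature at
4-pooled-sd separation and requires every true positive's posterior to
be at least 90% in each of 10 replicate seeds.

## Known limitations

- Headline counts of the original analysis (1515 selected genes, 14
  aggregated clusters, the 319-gene and 174-gene signatures, per-patient
  probabilities) depend on the deposited arrays plus filter settings that
  are not fully documented; this package reproduces the *procedures* and
  their statistical behaviour on planted-truth data, not those specific
  gene identities or counts.
- The chi-square stopping rule's `hierarchical` mode degenerates to
  k\* = 2 for symmetric well-separated clusters (see above); the exact
  construction of the criterion in the methodology it descends from is
  not published, and both implemented readings are candidates.
- The heterogeneity filter's placement (before vs after the fold-change
  gate) is a convention here, configurable but unverifiable.
- No array normalization, batch correction, functional annotation or
  gene-set enrichment: normalized matrices and annotated rearrangement
  tables are accepted as inputs.
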
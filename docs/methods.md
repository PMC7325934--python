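# Methods

`amplicore` implements a sub-OTU amplicon community analysis pipeline for
soils with a gradient of mercury contamination, together with the soil
geochemistry statistics that establish that gradient. This note documents
the models, parameter choices and numerical conventions, and what the
synthetic-data tests do and do not demonstrate.

## Sub-OTU feature construction

Reads are quality-controlled, dereplicated into unique sequences with
per-sample counts, and partitioned into *seeds* (total count >= 10) and
non-seeds. Each non-seed is merged into its nearest seed when their
global-alignment identity is at least 0.98; otherwise it is retained as an
independent feature. This sits between denoised exact variants and 97%
OTUs: abundant sequences anchor features and rare sequencing variants are
absorbed without transitive chaining (an independent non-seed never becomes
a merge target, so the seed/non-seed partition fixed at designation time
fully determines the table).

**Identity metric.** Identity is defined on a score-optimal global
alignment with end gaps penalized (match +1, mismatch -1, gap -2, linear
gaps) as matching columns divided by total alignment columns. For
equal-length sequences differing only by substitutions this reduces to the
fraction of agreeing positions. Alignment uses Biopython's
`PairwiseAligner`; an exact prefilter skips pairs that provably cannot
reach a threshold using the bound

    identity <= L_min / (L_min + d),

where `d` is the unit-cost edit distance (edlib) and `L_min` the shorter
length: every alignment has at most `L_min` matches and at least `d`
non-match columns. The prefilter is exact — the test suite asserts the
accelerated table is byte-identical to exhaustive all-pairs assignment.

**Ties.** An equidistant non-seed merges into the higher-count seed, then
the lexicographically smaller sequence. All orderings (dereplication,
seeds, features) are deterministic (count-descending, then lexicographic),
so outputs are reproducible byte for byte.

**Seed threshold scope.** The 10-count threshold is applied to counts
pooled across samples by default, which maximizes cross-sample
comparability of features; a per-sample mode is available
(`ClusterConfig(per_sample_seeds=True)`).

## Read preparation

Merged single-end amplicon reads are processed in this order: mean
per-base error (from phred+33 qualities) must not exceed 0.01 (FASTA input
skips this check); the forward primer must be found IUPAC-aware within 2
mismatches and is stripped together with everything 5' of it (reads
without it are discarded); the reverse-complemented reverse primer is
stripped when present but its absence is tolerated, since merged reads may
not span it; terminal N runs are trimmed and any internal N rejects the
read; trimmed reads shorter than 150 bp are discarded. The categories
partition the input exactly and the per-sample report asserts this.

**Chimera detection** runs on the dereplicated pool before clustering. A
sequence is flagged when two parents, each at least 2x more abundant,
admit a single breakpoint at which the left segment matches parent A and
the right segment parent B at >= 0.99 identity, while no single parent
explains the whole sequence at > 0.95 identity. Segment matching uses
positional mismatch profiles (cumulative mismatch counts from each end),
which assumes substitution-style divergence between chimera and parents —
correct for single-breakpoint crossovers of same-locus amplicons, the
mechanism the simulator implements and PCR chimera formation approximates.
It is a minimal two-parent crossover test, not a full partial-alignment
scoring model; indel-bearing chimeras would be missed. On simulated
error-free pools at 10% chimera rate it attains 100% sensitivity with no
false positives; sensitivity under sequencing error is not asserted.

## Taxonomy

Feature representatives are searched against a 7-rank, QIIME-style
lineage-annotated reference with the same identity metric and a 0.90
floor; below the floor a feature is unassigned. The best hit's lineage is
walked top-down and truncated before the first unnamed rank, so a
reference annotated to family only can never donate a genus. Two further
gates truncate the assignment depth: genus requires >= 0.97 identity and
species >= 0.99. Gates apply to the best hit; equal-identity ties resolve
to the lowest common named lineage of the tied hits. These invariants are
enforced at construction of every assignment object, not just tested.

## Abundance summaries

Total sum scaling divides each sample by its total (idempotent, columns
sum to 1). Feature filtering removes features that fail to reach count 4
in at least 20% of samples, then the lowest decile by inter-quartile range
of relative abundance; both knobs are configurable and the defaults follow
common practice of web-based microbiome pipelines. The core microbiome is
the set of taxa at >= 0.01% relative abundance in >= 20% of samples (a
strict 0.2% preset exists). Chao1 is the bias-corrected form
`S_obs + F1(F1-1)/(2(F2+1))`, defined even without doubletons; the classic
form is available by flag and the implementation is cross-checked against
scikit-bio. Heatmap display adds a pseudocount of half the smallest
nonzero relative abundance before the log and z-scores per feature
(constant features get z = 0); barplot display pools taxa with mean
relative abundance <= 1% into "Other", preserving column sums.

## Differential abundance

Counts are TMM-normalized (reference column = upper-quartile closest to
the mean; 30%/5% trimming on M/A values; precision-weighted mean; factors
normalized to geometric mean 1). A single common NB dispersion is
estimated by method of moments, `phi = median[(var - mean)/mean^2]`, on
normalized counts. Per feature, a likelihood-ratio test compares the
group-means NB model against the intercept-only model (for fixed
dispersion the NB mean MLE is the sample mean, so the fit is closed-form
and the whole test vectorizes), with p from chi-square on (groups - 1)
degrees of freedom. All-zero features get p = 1 and log2FC = 0. P-values
are BH-adjusted; significance is called at FDR 0.05. Fold-changes are
log2 ratios of normalized group means with pseudocount 0.5, reported
against the reference contamination level.

This is deliberately a common-dispersion NB-LRT, not an empirical-Bayes
tagwise fit: at the 5-10 samples per group typical of chamber designs the
chi-square approximation is mildly liberal (simulated null rejection
~5-7% at nominal 5%), which the calibration test brackets at [0.03, 0.07].
Because fold-changes are measured after normalization, effects planted in
a large fraction of features are partially absorbed by the normalization
itself (compositional closure); recovery simulations therefore plant
effects in a 10% minority.

## Multivariate analysis

Bray-Curtis dissimilarity (`1 - 2*sum(min)/sum(total)`) feeds three
procedures. PCoA Gower-centers the squared distances and
eigendecomposes; axes with negative eigenvalues (possible for semi-metric
input) are dropped with their count reported — no Lingoes/Cailliez
correction, matching the plain 2-D usage this pipeline serves — and
proportions explained are relative to the positive spectrum. Hierarchical
clustering offers group-average (UPGMA, ultrametric) and Ward linkage (the
squared-distance ward.D2 update), exported as newick with branch lengths.
PERMANOVA computes the pseudo-F from among/within sums of squared
distances and a permutation p-value `(1 + #{F_perm >= F_obs})/(1 + n_perm)`
with unrestricted label permutation, reproducible by seed and invariant to
sample order (samples are canonically sorted internally). Note the floor
`p = 1/(n_perm+1)` is attainable only when no permutation reproduces the
observed partition; with 5+5 samples ~0.8% of random permutations do, so
the practical minimum p is ~0.01 there, reaching 0.001 at 10+10.

CCA follows ter Braak: the taxon table is converted to the chi-square
standardized residual matrix `Q = (P - rc')/sqrt(rc')`, projected by
row-weighted least squares onto the environment variables (log(X+1)
transformed by default, then weighted-standardized), and the projection is
SVD-analyzed. Constrained eigenvalues lie in [0, 1], are bounded by the
corresponding unconstrained CA eigenvalues, and total inertia equals the
table's chi-square statistic over its grand total (verified against a
direct chi-square computation and against scikit-bio's CCA). Scores use
the scaling-2 convention (taxon scores scaled by singular values); biplot
scores are weighted correlations of the standardized environment variables
with the site axes. Constant environment columns are an error naming the
column; collinear columns are an error reporting the condition number.

## Geochemistry

The packaged five-site table carries moisture and loss-on-ignition (wt.%),
total C/N (g/kg), total P and KCl-extractable NH4/NO3/PO4 (mg/kg), and
THg/MeHg (ng/g dry weight). Below-detection entries are an explicit mask
("b.d." in CSV), never zeros: correlations exclude them pairwise (Pearson
on raw values, >= 3 complete pairs required), clustering imputes them at
half the variable's minimum observed value. ng/g is ppb, so ppm = ng/g /
1000. The MeHg fraction of a site set is the unweighted mean of per-site
100*MeHg/THg. Contamination binning uses THg cutoffs high >= 1000 ng/g and
medium >= 100 ng/g (configurable; chosen so the packaged table bins B as
high, S1 as medium and the rest low, with designated reference sites
labelled separately from metadata rather than by concentration). Site and
variable dendrograms use log(X+1) transformation, Bray-Curtis and
group-average linkage. On the packaged table MeHg averages 2.6% of THg at
the three low-THg sites but only ~0.1% at the two contaminated sites — the
fraction falls roughly an order of magnitude where THg is highest.

## Synthetic data

The simulator emulates the study design end-to-end: a toy reference of
well-separated random sequences (250 bp, all pairwise identities << 0.95,
a configurable fraction with unnamed genus/species to exercise
truncation), a factorial design of 4 contamination levels x 3 chamber
generations x 2 chamber types (24 samples at one replicate per cell), and
per-sample Dirichlet abundances (concentration 50 around the softmax of
normal(0,1) log-means) with optional per-taxon log-fold enrichment effects
keyed by level and/or generation — the mechanism for "metal-enriched taxa
rise with contamination and generation". Reads are forward primer +
per-taxon amplicon + reverse-complemented reverse primer with i.i.d.
substitutions (default 0.5%) and optional single-breakpoint two-parent
chimeras; qualities are constant Q40. 515F/926R (16S V4-V5) and
ITS1F/ITS2R presets are included. Every operation draws from its own RNG
stream derived from the config seed, so identical configs give
byte-identical FASTQ output.

Deliberate simplifications: amplicons are the whole toy reference (so
global identity to the true source is ~1), errors are uniform
substitutions with no indels or cycle-dependent quality structure, reads
are pre-merged, and the reference is complete for the community.
Passing recovery tests therefore demonstrate correctness of the
algorithms' logic under their stated assumptions — not classifier accuracy
on real 16S/ITS data against Silva/UNITE-scale references, where reference
incompleteness, length heterogeneity and indel error dominate.

## Problem sizes

Test and acceptance runs use 20-taxon references, 12-24 samples and
150-300 reads per sample (3-4k reads per run), 1000-feature differential
simulations, and 999-permutation PERMANOVA — sizes at which every
documented property is already exercised and the full suite runs in well
under a minute.
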
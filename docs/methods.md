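# Methods

`regulocate` implements the computational arc of a mutant-panel transcriptome
study in a bacterium with multiple replicons: starting from per-gene counts
for a panel of pathway mutants grown under two conditions, it finds the genes
that respond, clusters their fold-change profiles, discovers a shared
upstream binding motif de novo, scans the genome with it, and quantifies how
motif placement relates to the transcriptional effect — density along the
replicons, position within operons, and enrichment of candidate regulator
genes.  A synthetic-data generator produces genomes with planted motifs and
effects so that every stage can be validated against known truth without any
external download.

## The synthetic data model

The generator emulates the structure the analysis assumes rather than any
particular organism's sequence.  Three replicons (defaults 3.65 Mb, 1.35 Mb
and 1.68 Mb, mirroring the chromosome/megaplasmid/chromid proportions of a
rhizobial genome) are filled with uniform-random DNA and packed with genes
(defaults 1550/580/720; lengths uniform on 300–3,000 bp; every gap at least
250 bp).  Genes are grouped into operons whose sizes follow a categorical
distribution over 1–7 members (mean ≈ 2.4, singleton-heavy, as in bacterial
operon maps); operon members are contiguous on a shared strand, and order 1
is the promoter-proximal gene.

A contiguous *hot region* (default 120 kb on the megaplasmid-like replicon)
carries the regulatory signal: each operon lying wholly inside it receives,
with probability 0.9, one motif instance written into the 200 bp upstream of
its first gene, sampled column-wise from a PWM built from the palindromic
FixK-family consensus TTGAT-N4-ATCAA (informative positions at probability
0.97) and placed on a uniformly chosen strand — sampling, rather than
pasting a fixed string, gives the discovery stage realistic site degeneracy.
Decoy instances are placed intergenic-only elsewhere at 2 per Mb to exercise
density baselines.

Expression follows a planted effect model.  For an *affected* strain (eight
pathway mutants by default) under the *limited* condition only, a gene at
within-operon order k of a motif-bearing operon has true log2 fold change

    lfc = -beta * delta^(k-1) + Normal(0, sigma),   beta=3, delta=0.5, sigma=0.5;

everything else (the parent, the unaffected glgA1-like strain, the balanced
condition, motif-less operons) is exactly 0.  Counts are negative-binomial
(dispersion 0.1) around `abundance x length/1 kb x 2^lfc` with per-gene
log-normal abundances (log-mean ln 500, log-sd 1), two replicates per strain
and condition.  What the generator does *not* emulate: sequencing-error and
read-level artifacts, genome-scale base composition bias, operon read-through,
condition-dependent library composition.  Passing tests therefore demonstrate
that the pipeline recovers the planted structure under idealized noise, not
that it is robust to every artifact of real libraries.

## Differential expression

Counts are FPKM-normalized (`1e9 * count / (length * column total)`), the
log2 fold change is the ratio of group mean FPKMs (undefined when either
mean is 0), and a gene is tested only when its raw count summed over the
contrast reaches 10.  The test statistic operates on log2(FPKM+1).

With two replicates per group a per-gene Welch t has ~2 degrees of freedom;
its p-values cannot reach the ~1e-5 range that Benjamini–Hochberg correction
over thousands of genes demands, so a per-gene test would find nothing at
any effect size — the original tooling in this setting pools dispersion
information across genes for exactly this reason.  The default test is
therefore a moderated t: per-contrast pooled residual variances are shrunk
toward an F-distributed prior fitted across genes by method of moments on
the log scale, and the statistic is referred to a t distribution with
`d0 + df_residual` degrees of freedom.  The plain Welch t (with the
conventions p=1 for zero-variance/equal-means and p=0 for
zero-variance/unequal-means) remains available via `moderated=False`.
Significance is q <= 0.05 after BH over tested genes.

## Clustering

Genes significant in at least one mutant contrast form the expression
matrix (log2 fold changes; untested entries imputed as 0, since an absent
contrast carries no signal).  Complete-linkage agglomeration on Euclidean
distances gives the dendrogram; extraction is the two-threshold procedure:
cut into `top_k` clusters (default 2), then optionally re-cut the largest
cluster at a fixed height (default 7).  No row scaling is applied — the
clustered quantity is the raw log2 value.  The cluster feeding motif
discovery defaults to the one with the most negative mean profile across
affected-strain contrasts under the effect condition.

## Motif engine

**Scoring.** A PWM stores per-position probabilities over ACGT with a
0-order background (estimated strand-symmetrically from the input set);
windows score as log-odds in bits.

**Exact p-values.** The null score distribution is computed by dynamic
programming over a discretized score lattice (granularity 1e-4 bits):
column scores are rounded to lattice steps and convolved column by column.
A query threshold is mapped to the lattice with a slack of `width` steps so
that a k-mer achieving exactly the queried score is always counted; the
distribution is exact up to that discretization (verified against full
enumeration at every threshold the lattice resolves unambiguously).
Scanning inverts the tail once per matrix and threshold, reports both
strands on forward-strand 1-based inclusive coordinates, and skips windows
containing non-ACGT bases.

**Discovery.** The site model is ZOOPS — each sequence carries zero or one
site, uniform over positions and strands, against the 0-order background —
fit by EM.  Starts are seeded from `restarts` randomly chosen data k-mers
(seeded RNG), screened with an 8-iteration burn-in, and the two best
likelihoods are run to convergence (stop when the largest column change is
below 1e-4, cap 200 iterations; ties broken by first occurrence).  The
traced objective is the MAP objective (observed-data log-likelihood plus
the Dirichlet pseudocount prior), which EM increases monotonically — the
raw likelihood alone is not monotone under pseudocounted M-steps.  The best
motif per width over the search range (default 8–18) is kept, ranked by
E-value; reported sites are masked and the search repeats for up to
`n_motifs` motifs.

**E-value.** A deliberately simple, exactly testable surrogate for MEME's
statistic: each reported site's scan p-value is Sidak-corrected for the
number of windows in its sequence (best-of-m selection), the corrected
p-values are combined with the QFAST product-of-p formula
`P = p * sum_{k<n} (-ln p)^k / k!` (evaluated in log space), and the result
is multiplied by the number of (width, start, strand) configurations
searched.  Planted motifs in the validation data land far below the
conventional 1e-15 reporting threshold; the same search on unplanted input
sits tens to hundreds of orders of magnitude higher.  E-values smaller than
the double-precision floor are reported via `log10_e_value`.

**Comparison.** A query motif is aligned to each target over all offsets
with at least 4 shared columns in both orientations; similarity is the mean
Pearson r of aligned probability columns, with two conventions for
degenerate columns: (near-)identical columns agree perfectly (r=1; without
this a motif does not match itself when it contains uniform columns), and a
constant column against a non-constant one contributes 0.  The p-value is a
conditional permutation test: target columns are shuffled and the statistic
recomputed *at the observed offset and orientation*.  Re-maximizing the
alignment under the null was rejected: with a minimum overlap of 4 and the
degenerate column multiset of a short DNA motif, shuffled targets routinely
reach mean r ≈ 1 on minimal overlaps, and a perfect full-length match
becomes indistinguishable from noise.

## Co-localization

Motif-hit midpoints are smoothed with a Gaussian kernel (default bandwidth
30 kb, 1 kb grid, one unit of mass per hit so the track integrates to the
hit count; replicons are treated as linear, no edge correction — bias is
negligible when the bandwidth is far below the replicon length).  The
composite effect is the per-gene NA-skipping mean log2 fold change over a
named strain panel (default: the four synthesis mutants) under one
condition.  Per-gene density is the track value at the ORF midpoint, and
the headline statistic is the Pearson (and Spearman) correlation of density
with the composite effect.

Contiguous DE regions are detected by a run/gap/fraction rule (flagged genes
merged across gaps of at most 3 unflagged genes; kept when at least 5 genes
and at least half flagged) — the original study identified its regions by
inspection, so the rule and its parameters are exposed rather than claimed.
Motif-to-ORF distances are strand-aware (1 = immediately adjacent), use only
in-ORF-free hits, and are summarized by a 1-D Gaussian KDE.

## Operon-position statistics

Genes are classified by upstream-motif status of their transcription unit
(either hit orientation counts, multiple hits count as one, in-ORF hits are
ignored) into the four-group scheme (A singleton+motif, B singleton,
C operon+motif, D operon) and the five-group scheme (A/B/C = order 1/2/3 of
a motif-bearing unit, E = motif-less operon member, Z = motif-less
singleton); singletons are first-order, and members beyond order 3 are
reported but not tested.  In the pipeline the group analysis is confined to
genes inside detected DE regions, mirroring the restriction of the original
analysis to its candidate regions; genome-wide classification dilutes group
A with unaffected genes that carry chance upstream hits.  Group differences
use one-way ANOVA plus Tukey HSD (studentized-range adjusted p-values);
within-operon decay is the per-order mean with a strict-monotonicity flag.
Regulator enrichment is length-normalized, `(k/K) / (region_bp/genome_bp)`
— this is the normalization that reproduces the published 15.9-fold value,
as opposed to gene-count normalization, which does not — with an auxiliary
hypergeometric tail p when gene counts are supplied.

## Problem sizes and determinism

Validation runs the full default conditions: ~2,850 genes over 6.68 Mb, ten
strains x two conditions x two replicates, beta=3/delta=0.5/sigma=0.5,
dispersion 0.1.  Monte-Carlo checks use 10–20 seeded repetitions (20 for
motif recovery and decay statistics, 10 for the end-to-end closure and
co-localization); the acceptance script uses the same conditions with a
smaller number of repetitions and derives every stage seed from its single
`--seed` argument.  All randomness flows through seeded NumPy generators;
identical configuration and seed reproduce byte-identical artifacts
(hashed in the run manifest).

## Known limitations

- The E-value is not MEME's objective; only its reporting scale is aligned.
- The moderated test assumes roughly exchangeable per-gene variances after
  log transform; strong mean-variance structure in real data would call for
  a dedicated count model instead.
- The region detector depends on its run/gap parameters; it reproduces the
  planted truth region but was not tuned for fragmented real signals.
- Upstream windows are not truncated at neighbouring ORFs, and operon
  definitions are taken from the annotation, not predicted.
- Replicons are linear; circular wraparound is out of scope.
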
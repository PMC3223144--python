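# Methods

This note records the statistical procedures, the choices made where the
design was genuinely open, and what the synthetic validation does and does
not demonstrate. Nothing here reports a number the test suite or
`scripts/acceptance.py` does not itself compute.

## Preprocessing

**Quantile normalization.** Every array is mapped onto the common
distribution of per-rank cross-array means. Ties within an array receive
the mean of the reference values at their tied ranks, which makes the
transform idempotent. Note a structural property that matters for
interpretation: rank-based normalization can only preserve a true
expression shift if the surrounding distribution is dense; identical values
in two arrays can come back (slightly) different because each array's
empirical distribution differs elsewhere. On realistic data, with per-gene
abundances spanning several log2 units, the distortion is far below
biological effect sizes.

**Median polish.** Per feature, the replicate-probe block is fitted with
`value ~ overall + probe + array` by alternating row/column median sweeps
(row sweep first), stopping when the largest absolute residual change over
a full sweep drops below `tol` (default 1e-4, `max_iter` 10 — the de facto
standard for array summarization). The per-array summary is
`overall + array effect`. The absolute-residual objective is non-increasing
across sweeps; single-probe features pass through unchanged.

**Expressed calls.** A miRNA is expressed when its mean over the duplicate
arrays of at least `min_celltypes` cell types (default 1) exceeds
`min_mean` (default log2 intensity 6.0 on the normalized scale). The
threshold is exposed because expressed-call rules are never comparable
across array platforms.

## Differential expression

**Moderated t.** For a two-group contrast with n_a, n_b duplicate arrays,
the pooled residual variance s²_g has d_g = n_a + n_b − 2 df. The prior
(d₀, s₀²) is estimated by matching the first two moments of log s²_g to a
scaled log-F distribution (digamma/trigamma equations, Newton inversion of
the trigamma). The posterior variance is the precision-weighted blend
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), strictly between s²_g and s₀², and
t̃ = Δmean / (s̃_g √(1/n_a + 1/n_b)) is referred to d₀ + d_g df. When the
log-variances show no excess spread beyond sampling noise the prior df is
infinite and the prior variance is the plain average of the s²_g, so
identical variances shrink to themselves and the moderated t coincides with
the ordinary t. The implementation is checked in the test suite against R's
`limma::eBayes` on the same design (agreement ≤ 1e-9) and against a
parameter-recovery simulation (d₀ within ±1, s₀² within ±20% at 2000
features).

Duplicate arrays of one RNA sample are treated as independent replicates
within their group; a constructor flag collapses duplicates to per-sample
means first for users who prefer the conservative reading.

**Multiclass SAM.** For K groups of sizes n_k (N = Σn_k),

    r_i = sqrt( (N / Π n_k) · Σ_k n_k (x̄_ik − x̄_i)² )
    s_i = sqrt( (Σ_k 1/n_k) / (Σ_k (n_k−1)) · Σ_k Σ_j (x_ikj − x̄_ik)² )
    d_i = r_i / (s_i + s₀),

which reduces to the classic two-class statistic at K = 2. The fudge
factor s₀ is chosen from the 0–100th percentiles of s (step 5) by
minimizing the coefficient of variation of the windowed median-absolute
deviation of d across s-quantile windows (windows hold ≥ 25 features).
Because that CV landscape is nearly flat on feature sets of a few hundred,
candidates within 5% of the minimum are treated as ties and the largest s₀
wins: damping small-variance artifacts is conservative, amplifying them is
not. The null is built from group-label permutations (exhaustive when the
number of distinct assignments is below the requested count, sampled
otherwise); for each threshold Δ the cutoff is the smallest sorted d whose
deviation from the mean permuted order statistic reaches Δ, the FDR is the
median permuted exceedance count over the observed count, and the reported
set is taken at the smallest Δ with FDR at or below the configured level
(default 0.05).

**Clustering and Venn.** Sample profiles are clustered with average linkage
on 1 − Pearson r; leaf order is made deterministic by rotating each subtree
so the lexicographically smallest label leads. Zero-variance features are
dropped with a log entry. The Venn partition assigns each feature to one of
the 2³ − 1 significance-pattern regions over three lineage comparisons at
unadjusted p < α.

## Genomic clusters

Loci are chained per chromosome by single linkage: consecutive loci join
one cluster iff the gap (next start − previous end) is at most the
threshold, 10,000 bp by default — the miRBase-style convention; strand is
ignored unless the co-stranded flag is set, and an exclusion list handles
array-indistinguishable homologs. Cluster-level differential expression
combines member evidence with Stouffer's method: z_i = Φ⁻¹(1 − p_i/2) ·
sign(logFC_i), Z = Σz_i/√m, two-sided p, BH-adjusted across the full
(cluster × comparison) family (Bonferroni by flag). How a published
cluster-level "Z score" was computed is rarely stated; the Stouffer reading
was chosen because member-level signed significance is exactly what the
moderated-t stage provides, and it has a closed-form null the tests
exercise. The re-test drops members with unadjusted p < α and recombines
the remainder; an emptied cluster is flagged as fully driven by its
individual members. Member p-values are clipped at 1e-300 before the normal
inverse so extreme members stay finite. Clusters of size 1 are excluded
from testing by default.

## Seed-enrichment landscapes

The target word of a miRNA is the DNA reverse complement of the 5'-most k
nucleotides of its mature sequence, k ∈ {6, 7, 8}, making the shorter words
nested suffixes of the 8-mer. (Anchoring at position 1 rather than the
2–8 "seed" offset follows the word convention of the family sites this
convention reproduces; families sharing a site can additionally be declared
explicitly in the word map, since one word may serve several related
miRNAs.) Occurrences are counted overlapping, single-stranded.

For a gene list ranked by mean log2 difference (ties broken by gene id,
genes without a usable UTR dropped with a log entry), the landscape value
at a cutpoint (leading windows of ⌈iN/n_bins⌉ genes, n_bins = 50) is the
signed −log10 of the smaller hypergeometric tail: population = all k-mer
positions, successes = all occurrences of the word, sample = positions in
the window, observed = occurrences in the window; positive sign means
enrichment in the leading window. The peak is the cutpoint of largest
|value|; tail probabilities are floored at 1e-320 before the log. Counting
k-mer positions (not genes containing the word) is the primary mode; a
genes-containing mode exists for sensitivity checks. No nucleotide
composition-bias correction is applied — a deliberate simplification
relative to full Sylamer, documented as a limitation.

**Genes under a peak** are the word-containing genes on the enriched side:
the leading window when the peak is positive, the trailing genes when it is
negative (a negative peak *is* trailing-end enrichment; returning the
leading window there would name exactly the genes without the signal).
A peak that misses the significance cutoff returns the empty set.

## Census, resampling, concordance

An instance is one (comparison, word length, miRNA) whose word has peak
p ≤ 10⁻⁴; a word shared by several miRNAs credits each of them, and one
word significant at two lengths counts twice — word lengths are separate
analyses. The universe is every miRNA with a derivable seed word on the
annotation. The trio statistic is the number of instances credited to the
three chosen miRNAs (by default the SAM-significant set when it has exactly
three members); the null redraws 3 miRNAs uniformly without replacement
10,000 times and the empirical p uses the +1/(n+1) correction so it is
never exactly zero.

Concordance: for an instance from comparison A−B (ranked most-up-in-A
first), a trailing peak marks enrichment among genes down in A, which is
the direction repression predicts when the miRNA is higher in A; a leading
peak predicts the miRNA higher in B. Instances with exactly tied miRNA
means are indeterminate and leave the denominator.

## The synthetic generator

The generator emulates the study design the chain assumes: 7 cell-type
cultures (default labels HUVEC, HAEC, HCEC, HPAEC, HPMVEC, HDMVEC, HBMVEC),
one RNA sample each, hybridized in duplicate; 200 miRNAs of which ~25% are
low-intensity background (abundance ~U(3.25, 4.75)) and the rest expressed
(abundance ~U(7, 11)); 20 genomic clusters of 2–5 members with exact 2 kb
intra-cluster gaps and 10× gaps between blocks; per-(cluster, cell type)
shared effects (SD 0.02); a planted trio of variable miRNAs drawn from
three distinct clusters, each elevated by 1.0 log2 (≈ 2-fold, the scale
such discriminating miRNAs show) in 3 of the 7 cell types; i.i.d. array
noise SD 0.10, a realistic technical-replicate spread for duplicate
hybridizations of one high-quality RNA sample. The mRNA side plants
15% of 2000 genes as targets (split round-robin across the trio), inserts
1–3 copies of the owning miRNA's 8-mer word per target UTR,
rejection-samples all other UTR content free of every trio word, and
represses each target by repression_effect × miRNA excess in the affected
cell types. UTR base composition defaults to uniform and is a knob so
composition-bias sensitivity can be explored. Three RNG streams
(annotation, arrays, UTRs) derive from the master seed so regenerating one
artifact leaves the others untouched.

Default magnitudes were fixed from a design-time power analysis of the
multiclass SAM statistic under the duplicate design: the null d
distribution is scale-free, so recovery margins are set by effect/noise
(trio) and cluster-effect/noise (the members that must *not* reach
individual significance); the defaults give exact trio recovery with large
margin across seed sweeps. The per-feature abundance spread is not
cosmetic: without it, rank-based normalization flattens planted shifts at
the sparse extremes of the intensity distribution. The trio is kept in the
mid-abundance range for the same reason.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: probe-level Agilent feature-extraction artifacts
(generation starts at probe summaries, with an optional replicate-probe
layer for median polish), correlated noise between duplicates beyond the
shared sample signal, biased UTR base composition (by default), words
occurring in non-target UTRs at background rates (the sterile rejection
construction makes other trio words *depleted* wherever one member's
target block concentrates — those depletion instances are real
signed-landscape events, but their direction carries no repression
information, which is why the default-noise concordance sits below 1.0),
miRNA families sharing seeds (mature sequences are drawn with distinct 5'
8-mers), and cross-hybridizing homologs.

## Problem sizes

Defaults were chosen so that a full chain run — 200 miRNAs × 14 arrays,
2000 genes, 21 comparisons × 3 word lengths (≈ 7,500 landscapes), 1000 SAM
permutations, 10,000 resampling draws — completes in well under a minute on
one CPU, with seed sweeps showing exact trio recovery throughout. All
stages scale linearly in the number of landscapes and permutations for
users who want larger panels.

## Known limitations

- The Stouffer construction is one defensible reading of cluster-level
  "Z scores"; published tables computed differently will not be reproduced
  numerically, only qualitatively.
- No composition-bias correction in the landscapes; AT-rich UTRs will
  inflate AT-rich words on real data.
- The expressed-call threshold is platform-specific and has no universal
  default.
- Quantile normalization cannot preserve exact cross-array ties, so
  noise-free synthetic constructions score concordance against the
  generator's own means.
- The pairwise moderated t covers single two-group contrasts only; there is
  no general design-matrix machinery.
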
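# seedscape

Discovering cell-type-discriminating microRNAs from expression arrays and
their downstream target signatures in mRNA data.

Closely related primary cell cultures — for example endothelial cells taken
from umbilical vein (HUVEC), aorta (HAEC), coronary artery (HCEC) or the
microvasculature — share most of their miRNA repertoire, and the few miRNAs
that do differ are candidates for conferring site-specific phenotype.
Finding them takes a chain of analyses, each individually standard, that has
to work end to end: array preprocessing, two flavors of differential
expression, genomic context, and sequence-level confirmation in independent
mRNA data. `seedscape` implements that chain as a tested, reusable library
with a synthetic-study generator so every stage can be validated against
planted ground truth.

## The chain

1. **Preprocessing** (`seedscape.expression`) — quantile normalization
   across arrays plus Tukey median-polish summarization of replicate probes
   (the RMA recipe without background correction), expressed-miRNA calls
   over duplicate arrays, and a ΔΔCt helper for qPCR follow-up.
2. **Pairwise moderated t** (`seedscape.diffexp`) — empirical-Bayes variance
   moderation: s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) with (d₀, s₀²) fitted by
   matching the moments of log s²_g to a scaled log-F; t̃ is referred to
   d₀ + d_g degrees of freedom. Verified to machine precision against an
   independent reference implementation. Plus BH adjustment, 1 − r Pearson
   average-linkage clustering, and a three-way Venn partition of
   significance patterns.
3. **Multiclass SAM** (`seedscape.sam`) — d_i = r_i/(s_i + s₀) with a
   fudge factor chosen by the coefficient-of-variation rule and false
   discovery rates estimated from group-label permutations; the significant
   set is taken at the smallest threshold Δ with estimated FDR ≤ 0.05.
4. **Polycistronic clusters** (`seedscape.clusters`) — chromosomal miRNA
   clusters chained at a ≤ 10 kb inter-locus gap; cluster-level differential
   expression by Stouffer's Z = Σz_i/√m over signed member scores, with a
   re-test after removing individually significant members.
5. **Seed-enrichment landscapes** (`seedscape.seedscan`) — the k-mer target
   word of a miRNA (reverse complement of its 5'-most k nt, k ∈ {6, 7, 8});
   signed −log10 hypergeometric tail p of the word's occurrence count in
   growing leading windows of a rank-ordered gene list.
6. **Census and resampling** (`seedscape.census`) — every (comparison,
   word length, miRNA) instance with peak p ≤ 10⁻⁴, the trio's instance
   count against 10,000 random 3-miRNA draws, and the directional
   concordance between miRNA expression and the repressed end of each
   ranking.
7. **Synthetic studies** (`seedscape.synthetic`) — duplicate arrays over a
   7-culture panel, per-feature abundances, polycistron-correlated effects, a
   planted variable trio, and 3'UTRs in which planted target genes carry the
   trio's seed words and are repressed where the miRNA is high.

`seedscape.pipeline.run_all` executes the whole chain from one seeded config
and writes a JSON report; the `seedscape` command exposes each stage.

## Worked example

```python
from seedscape import PipelineConfig, run_all
from seedscape.synthetic import SyntheticConfig

config = PipelineConfig(synthetic=SyntheticConfig(rng_seed=1), rng_seed=1)
result = run_all(config)

print(result.sam_results.summary())
stages = result.report["stages"]
print("expressed:", stages["expressed_call"]["n_expressed"])
print("census instances:", stages["census"]["n_instances"])
print("trio instances:", stages["resample"]["observed_instances"],
      "empirical p:", stages["resample"]["empirical_p"])
print("concordant fraction:", round(stages["concordance"]["fraction"], 3))
```

prints

```
Multiclass SAM over 150 features, s0 = 0.3374, 1000 sampled permutations
delta = 0.009632 (FDR <= 0.05): 3 significant features
significant: miR-001, miR-028, miR-033
expressed: 150
census instances: 229
trio instances: 171 empirical p: 9.999000099990002e-05
concordant fraction: 0.825
```

Reading the numbers: of 200 simulated miRNAs, 150 pass the expressed call
(the planted expressed set); SAM at FDR ≤ 0.05 returns exactly the three
planted variable miRNAs; across all 21 cell-type comparisons × 3 word
lengths, 229 seed words reach peak p ≤ 10⁻⁴ of which 171 belong to the
planted trio — an excess no random 3-miRNA draw matched in 10,000 tries
(empirical p ≈ 10⁻⁴) — and in 82% of decided instances the culture with the
higher miRNA carried the enrichment on its repressed side. The discordant
minority are instances from comparisons where the miRNA barely differs, for
which the direction is uninformative.

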
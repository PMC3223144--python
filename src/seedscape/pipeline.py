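"""End-to-end orchestration: simulate -> normalize -> call -> test -> census.

``run_all`` executes the whole inference chain on a synthetic study (or on
user-supplied tables) and writes a machine-readable JSON report with every
stage's headline numbers plus the seeds and config hash, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import census as census_mod
from . import clusters as clusters_mod
from . import seedscan
from .diffexp import ModeratedT, ModeratedTResults
from .expression import ExpressionMatrix, call_expressed, median_polish_summarize, quantile_normalize
from .sam import SAM
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]


@dataclass
class PipelineConfig:
    """Constants of the inference chain.

    The defaults are the chain's standard operating points: unadjusted
    alpha 0.05 for pairwise calls, SAM FDR 0.05 with 1000 permutations,
    10 kb cluster gap, landscape cutoff 1e-4 for word lengths 6/7/8,
    and 10,000 resampling draws.
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    expressed_min_mean: float = 6.0
    expressed_min_celltypes: int = 1
    alpha: float = 0.05
    sam_permutations: int = 1000
    sam_fdr_level: float = 0.05
    cluster_gap_bp: int = 10_000
    cluster_alpha: float = 0.05
    sylamer_cutoff: float = 1e-4
    word_lengths: tuple[int, ...] = (6, 7, 8)
    n_bins: int = 50
    resampling_draws: int = 10_000
    trio: tuple[str, ...] | None = None  # None: SAM-significant set when it is a trio
    comparisons: tuple[tuple[str, str], ...] | None = None  # None: all unordered pairs
    run_sam: bool = True
    rng_seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.sam_fdr_level < 1:
            raise ValueError("alpha levels must be in (0,1)")
        if not 0 < self.sylamer_cutoff < 1:
            raise ValueError("sylamer_cutoff must be in (0,1)")
        if self.cluster_gap_bp <= 0:
            raise ValueError("cluster_gap_bp must be > 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        self.synthetic.validate()

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything the chain produced, plus the JSON-able report."""

    config: PipelineConfig
    dataset: SyntheticDataset
    normalized: ExpressionMatrix
    expressed: set[str]
    pairwise: dict[str, ModeratedTResults]
    sam_results: object | None
    clusters: list
    cluster_table: pd.DataFrame
    cluster_retest: pd.DataFrame
    ranked_lists: dict[str, "seedscan.RankedGeneList"]
    landscapes: dict
    census: census_mod.EnrichmentCensus
    resampling: census_mod.ResamplingResult | None
    concordance_fraction: float
    concordance_table: pd.DataFrame
    trio: list[str]
    report: dict

    def write_report(self, path) -> None:
        Path(path).write_text(json.dumps(self.report, indent=1, sort_keys=True) + "\n")


def _pairwise_comparisons(cell_types: list[str], explicit) -> list[tuple[str, str]]:
    if explicit is not None:
        return [tuple(c) for c in explicit]
    return [(a, b) for i, a in enumerate(cell_types) for b in cell_types[i + 1 :]]


def run_all(config: PipelineConfig | None = None, outdir=None) -> PipelineResult:
    """Run the full chain on a synthetic study under one config and seed."""
    config = config or PipelineConfig()
    config.validate()
    report: dict = {
        "config_hash": config.content_hash(),
        "rng_seed": config.rng_seed,
        "stages": {},
    }

    # 1. simulate
    synth_cfg = config.synthetic
    dataset = generate_dataset(synth_cfg)
    truth = dataset.truth
    report["stages"]["simulate"] = {
        "n_mirnas": synth_cfg.n_mirnas,
        "n_cell_types": synth_cfg.n_cell_types,
        "n_arrays": len(dataset.mirna_matrix.array_ids),
        "n_genes": synth_cfg.n_genes,
        "rng_seed": synth_cfg.rng_seed,
    }
    log.info("simulate: %d miRNAs x %d arrays", synth_cfg.n_mirnas, len(dataset.mirna_matrix.array_ids))

    # 2. normalize (quantile + optional median-polish probe summarization)
    if dataset.probe_matrix is not None:
        probe_norm = quantile_normalize(dataset.probe_matrix)
        probe_map = {p: p.rsplit("_p", 1)[0] for p in probe_norm.values.index}
        normalized = median_polish_summarize(probe_norm, probe_map)
        normalized = ExpressionMatrix(
            normalized.values.loc[sorted(normalized.values.index)],
            dict(normalized.sample_of_array),
            dict(normalized.cell_type_of_sample),
        )
    else:
        normalized = quantile_normalize(dataset.mirna_matrix)
    report["stages"]["normalize"] = {
        "n_features": len(normalized.feature_ids),
        "median_polish": dataset.probe_matrix is not None,
    }

    # 3. expressed call
    expressed = call_expressed(normalized, config.expressed_min_mean, config.expressed_min_celltypes)
    expr_matrix = normalized.subset_features(sorted(expressed))
    report["stages"]["expressed_call"] = {
        "min_mean": config.expressed_min_mean,
        "min_celltypes": config.expressed_min_celltypes,
        "n_expressed": len(expressed),
    }
    log.info("expressed call: %d of %d", len(expressed), len(normalized.feature_ids))

    # 4. pairwise moderated t
    cell_types = expr_matrix.cell_types
    comparisons = _pairwise_comparisons(cell_types, config.comparisons)
    pairwise: dict[str, ModeratedTResults] = {}
    variable: set[str] = set()
    for a, b in comparisons:
        res = ModeratedT(expr_matrix, a, b).fit()
        pairwise[f"{a}-{b}"] = res
        variable |= res.significant(config.alpha)
    report["stages"]["pairwise"] = {
        "n_comparisons": len(comparisons),
        "alpha": config.alpha,
        "n_variable": len(variable),
    }
    log.info("pairwise moderated t: %d variable miRNAs at p < %g", len(variable), config.alpha)

    # 5. SAM across all cell types
    sam_results = None
    sam_significant: set[str] = set()
    if config.run_sam:
        sam_results = SAM(expr_matrix).fit(
            n_permutations=config.sam_permutations,
            rng_seed=config.rng_seed,
            fdr_level=config.sam_fdr_level,
        )
        sam_significant = set(sam_results.significant)
        report["stages"]["sam"] = {
            "n_permutations": sam_results.n_permutations,
            "s0": sam_results.s0,
            "chosen_delta": sam_results.chosen_delta,
            "sam_significant": sorted(sam_significant),
        }
        log.info("SAM: %d significant at FDR <= %g", len(sam_significant), config.sam_fdr_level)

    # 6. genomic clusters
    detected = clusters_mod.detect_clusters(dataset.loci, config.cluster_gap_bp)
    cluster_table = clusters_mod.cluster_test_table(detected, pairwise)
    significant_rows = cluster_table[cluster_table["Adj.P.value"] <= config.cluster_alpha]
    retest_rows = []
    by_id = {c.cluster_id: c for c in detected}
    for _, row in significant_rows.iterrows():
        res = clusters_mod.retest_without_significant(
            by_id[row["Cluster"]],
            pairwise[row["Comparison"]],
            alpha=config.cluster_alpha,
            comparison=row["Comparison"],
        )
        retest_rows.append(
            (res.cluster_id, res.comparison, res.z_score, res.p_value,
             len(res.members_removed), res.fully_driven_by_individuals)
        )
    cluster_retest = pd.DataFrame(
        retest_rows,
        columns=["Cluster", "Comparison", "Z.score", "P.value", "n_removed", "fully_driven"],
    )
    if len(cluster_retest):
        mask = cluster_retest["P.value"].notna()
        adj = np.full(len(cluster_retest), np.nan)
        if mask.any():
            from .diffexp import benjamini_hochberg

            adj[mask.to_numpy()] = benjamini_hochberg(cluster_retest.loc[mask, "P.value"].to_numpy())
        cluster_retest["Adj.P.value"] = adj
    report["stages"]["clusters"] = {
        "gap_bp": config.cluster_gap_bp,
        "n_clusters_detected": len(detected),
        "n_multi_member": sum(1 for c in detected if c.size >= 2),
        "n_tests": len(cluster_table),
        "n_significant": int(len(significant_rows)),
        "n_significant_after_removal": int(
            (cluster_retest["Adj.P.value"] <= config.cluster_alpha).sum()
        ) if len(cluster_retest) else 0,
    }

    # 7. seed-enrichment landscapes
    mrna_means = dataset.mrna_matrix.cell_type_means()
    word_map = seedscan.build_seed_word_map(dataset.mature_sequences, ks=tuple(config.word_lengths))
    ranked: dict[str, seedscan.RankedGeneList] = {}
    landscapes: dict[tuple[str, int], dict[str, seedscan.EnrichmentLandscape]] = {}
    counts_by_k = {
        k: seedscan.count_words_in_utrs(dataset.utrs, set(word_map[k]), k)
        for k in config.word_lengths
    }
    for a, b in comparisons:
        rl = seedscan.rank_genes(mrna_means, a, b, utrs=dataset.utrs)
        ranked[rl.comparison] = rl
        for k in config.word_lengths:
            counts, positions = counts_by_k[k]
            landscapes[(rl.comparison, k)] = {
                w: seedscan.hypergeometric_landscape(rl, w, counts[w], positions, n_bins=config.n_bins)
                for w in counts.columns
            }
    report["stages"]["seedscan"] = {
        "word_lengths": list(config.word_lengths),
        "n_bins": config.n_bins,
        "n_landscapes": sum(len(v) for v in landscapes.values()),
    }

    # 8. census
    universe = set(dataset.mature_sequences)
    the_census = census_mod.build_census(landscapes, word_map, universe, config.sylamer_cutoff)
    report["stages"]["census"] = {
        "p_cutoff": config.sylamer_cutoff,
        "n_instances": the_census.n_instances,
        "n_distinct_mirnas": the_census.n_distinct_mirnas,
        "universe_size": len(universe),
    }
    log.info("census: %d instances from %d miRNAs", the_census.n_instances, the_census.n_distinct_mirnas)

    # 9. trio resampling
    if config.trio is not None:
        trio = sorted(config.trio)
    elif len(sam_significant) == 3:
        trio = sorted(sam_significant)
    else:
        trio = sorted(truth.variable_trio)
    resampling = census_mod.trio_resampling_test(
        the_census, set(trio), n_draws=config.resampling_draws, rng_seed=config.rng_seed
    )
    report["stages"]["resample"] = {
        "trio": trio,
        "observed_instances": resampling.observed,
        "n_draws": resampling.n_draws,
        "empirical_p": resampling.empirical_p,
    }

    # 10. directional concordance for the trio's instances
    trio_instances = [i for i in the_census.instances if i.mirna_id in set(trio)]
    mirna_means = expr_matrix.cell_type_means()
    known = [i for i in trio_instances if i.mirna_id in mirna_means.index]
    frac, conc_table = census_mod.directional_concordance(known, mirna_means)
    report["stages"]["concordance"] = {
        "n_instances": len(known),
        "n_concordant": int(conc_table["concordant"].dropna().sum()) if len(conc_table) else 0,
        "fraction": None if np.isnan(frac) else frac,
    }

    result = PipelineResult(
        config=config,
        dataset=dataset,
        normalized=normalized,
        expressed=expressed,
        pairwise=pairwise,
        sam_results=sam_results,
        clusters=detected,
        cluster_table=cluster_table,
        cluster_retest=cluster_retest,
        ranked_lists=ranked,
        landscapes=landscapes,
        census=the_census,
        resampling=resampling,
        concordance_fraction=frac,
        concordance_table=conc_table,
        trio=trio,
        report=report,
    )

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        dataset.write(out / "synthetic")
        normalized.to_tsv(out / "normalized_matrix.tsv", comment=f"config {config.content_hash()}")
        cluster_table.to_csv(out / "cluster_tests.tsv", sep="\t", index=False)
        if len(cluster_retest):
            cluster_retest.to_csv(out / "cluster_tests_retest.tsv", sep="\t", index=False)
        the_census.to_frame().to_csv(out / "census.tsv", sep="\t", index=False)
        resampling.histogram().to_csv(out / "resampling_histogram.tsv", sep="\t")
        conc_table.to_csv(out / "concordance.tsv", sep="\t", index=False)
        result.write_report(out / "report.json")
    return result
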
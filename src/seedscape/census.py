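"""Census of significant seed enrichments and the trio resampling test.

Across every (cell-type comparison, word length) landscape set, each word
whose peak reaches the significance cutoff contributes one census instance
per miRNA sharing that word.  The observed number of instances credited to
a chosen miRNA trio is then compared to a null in which 3 miRNAs are drawn
uniformly without replacement from the word-bearing universe; the
empirical p uses the +1/(n+1) correction so it can never be exactly 0.
The directional concordance check asks, per trio instance, whether the
cell type with the higher miRNA expression is the one whose down-regulated
genes carry the enrichment peak - the direction miRNA repression predicts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seedscan import EnrichmentLandscape, RankedGeneList

log = logging.getLogger(__name__)

__all__ = [
    "CensusInstance",
    "EnrichmentCensus",
    "ResamplingResult",
    "build_census",
    "trio_resampling_test",
    "directional_concordance",
]


@dataclass(frozen=True)
class CensusInstance:
    comparison: str
    k: int
    mirna_id: str
    word: str
    peak_p: float
    peak_sign: int  # +1 leading-window enrichment, -1 trailing


@dataclass
class EnrichmentCensus:
    """The set of significant (comparison, k, miRNA) enrichment instances."""

    instances: list[CensusInstance]
    universe: set[str]
    p_cutoff: float
    unannotated_words: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    @property
    def n_distinct_mirnas(self) -> int:
        return len({i.mirna_id for i in self.instances})

    def count_for(self, mirnas: set[str]) -> int:
        return sum(1 for i in self.instances if i.mirna_id in mirnas)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (i.comparison, i.k, i.word, i.mirna_id, i.peak_p, i.peak_sign)
                for i in self.instances
            ],
            columns=["comparison", "k", "word", "mirna_id", "peak_p", "peak_sign"],
        )


def build_census(
    landscapes: dict[tuple[str, int], dict[str, EnrichmentLandscape]],
    seed_word_map: dict[int, dict[str, set[str]]],
    universe: set[str],
    p_cutoff: float = 1e-4,
) -> EnrichmentCensus:
    """Collect significant instances from landscapes per (comparison, k).

    ``landscapes[(comparison, k)]`` maps words to landscapes.  A word whose
    peak p is at or below the cutoff fans out to every miRNA sharing it in
    ``seed_word_map[k]``; words with no mapped miRNA are logged and tallied
    as unannotated.  Keys are processed in sorted order so the census does
    not depend on supply order.
    """
    instances: list[CensusInstance] = []
    unannotated: list[tuple[str, int, str]] = []
    seen: set[tuple[str, int, str]] = set()
    for comparison, k in sorted(landscapes):
        for word in sorted(landscapes[(comparison, k)]):
            lsc = landscapes[(comparison, k)][word]
            if lsc.flat or lsc.peak_p > p_cutoff:
                continue
            sharing = seed_word_map.get(k, {}).get(word)
            if not sharing:
                log.warning("significant word %s (k=%d, %s) has no miRNA annotation", word, k, comparison)
                unannotated.append((comparison, k, word))
                continue
            sign = 1 if lsc.peak_value >= 0 else -1
            for mirna_id in sorted(sharing):
                key = (comparison, k, mirna_id)
                if key in seen:
                    continue
                seen.add(key)
                instances.append(
                    CensusInstance(comparison, k, mirna_id, word, lsc.peak_p, sign)
                )
    return EnrichmentCensus(instances, set(universe), p_cutoff, unannotated)


@dataclass
class ResamplingResult:
    """Null distribution of trio instance counts from random 3-miRNA draws."""

    observed: int
    null_counts: np.ndarray
    empirical_p: float
    n_draws: int
    rng_seed: int
    draw_size: int = 3

    def histogram(self) -> pd.Series:
        vals, counts = np.unique(self.null_counts, return_counts=True)
        return pd.Series(counts, index=vals, name="n_draws")

    def summary(self) -> str:
        return (
            f"trio resampling: observed {self.observed} instances; "
            f"{self.n_draws} draws of {self.draw_size}; "
            f"empirical p = {self.empirical_p:.3g} "
            f"(max null count {int(self.null_counts.max())})"
        )


def trio_resampling_test(
    census: EnrichmentCensus,
    trio: set[str],
    n_draws: int = 10_000,
    rng_seed: int = 0,
) -> ResamplingResult:
    """Permutation null for the trio's census instance count.

    Draws ``n_draws`` uniform 3-miRNA subsets of the universe, recounts the
    census instances credited to each subset, and reports
    p = (1 + #{count >= observed}) / (n_draws + 1).
    """
    trio = set(trio)
    if not trio <= census.universe:
        raise ValueError("trio not contained in the miRNA universe")
    if len(census.universe) < 3:
        raise ValueError("universe smaller than the draw size")
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000 for a stable empirical p")
    observed = census.count_for(trio)
    universe = np.array(sorted(census.universe))
    per_mirna = pd.Series(0, index=universe, dtype=np.int64)
    for inst in census.instances:
        if inst.mirna_id in per_mirna.index:
            per_mirna[inst.mirna_id] += 1
    counts_arr = per_mirna.to_numpy()
    rng = np.random.default_rng(rng_seed)
    draws = np.empty(n_draws, dtype=np.int64)
    n_universe = universe.size
    for i in range(n_draws):
        idx = rng.choice(n_universe, size=3, replace=False)
        draws[i] = counts_arr[idx].sum()
    p = (1.0 + float((draws >= observed).sum())) / (n_draws + 1.0)
    return ResamplingResult(observed, draws, p, n_draws, rng_seed)


def directional_concordance(
    instances: list[CensusInstance],
    mirna_cell_means: pd.DataFrame,
) -> tuple[float, pd.DataFrame]:
    """Fraction of instances where enrichment sits at the repressed end.

    For an instance from comparison "A-B" (ranking most-up-in-A first), a
    trailing peak (sign -1) marks enrichment among genes down in A, which
    is concordant when the miRNA's mean expression is higher in A; a
    leading peak (sign +1) marks genes up in A (down in B), concordant when
    the miRNA is higher in B.  Instances with tied miRNA means are marked
    indeterminate and excluded from the denominator.
    """
    rows = []
    for inst in instances:
        a, _, b = inst.comparison.partition("-")
        mu_a = float(mirna_cell_means.loc[inst.mirna_id, a])
        mu_b = float(mirna_cell_means.loc[inst.mirna_id, b])
        if mu_a == mu_b:
            rows.append((inst.comparison, inst.k, inst.mirna_id, None))
            continue
        high = a if mu_a > mu_b else b
        repressed_end_cell = a if inst.peak_sign < 0 else b
        rows.append((inst.comparison, inst.k, inst.mirna_id, high == repressed_end_cell))
    table = pd.DataFrame(rows, columns=["comparison", "k", "mirna_id", "concordant"])
    decided = table["concordant"].dropna()
    fraction = float(decided.mean()) if len(decided) else float("nan")
    return fraction, table
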
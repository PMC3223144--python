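"""Seed-word enrichment landscapes along ranked gene lists.

A miRNA's canonical 3'UTR target site is the reverse complement of its 5'
seed; here the k-mer word (k in {6, 7, 8}) is the DNA reverse complement of
the 5'-most k nucleotides of the mature sequence, so e.g. mature
CAAAGUGCUCAUAGUGCAGGUAG gives the 8-mer GCACTTTG.  Genes are rank-ordered
by an expression difference, and for growing leading windows the word's
occurrence count is compared to its genome-wide count with a hypergeometric
tail test; the signed -log10 p landscape peaks where targets concentrate.
The counting unit is k-mer positions (overlapping occurrences), following
the Sylamer statistic; a genes-containing-word mode exists for sensitivity
checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

log = logging.getLogger(__name__)

__all__ = [
    "RankedGeneList",
    "EnrichmentLandscape",
    "derive_seed_words",
    "build_seed_word_map",
    "count_word_occurrences",
    "count_words_in_utrs",
    "hypergeometric_landscape",
    "landscape_grid",
    "genes_under_peak",
    "rank_genes",
]

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def derive_seed_words(mature_sequence: str, k: int) -> str:
    """Reverse complement of the 5'-most ``k`` nucleotides, in DNA alphabet.

    Works for RNA or DNA input; ambiguity codes are rejected because a
    degenerate seed has no single target word.
    """
    seq = _to_dna(mature_sequence)
    if len(seq) < k:
        raise ValueError(f"mature sequence shorter than k={k}")
    head = seq[:k]
    if any(b not in "ACGT" for b in head):
        raise ValueError(f"ambiguous base in seed region {head!r}")
    return head.translate(_DNA_COMPLEMENT)[::-1]


def build_seed_word_map(
    mature_sequences: dict[str, str],
    ks: tuple[int, ...] = (6, 7, 8),
    explicit: dict[int, dict[str, set[str]]] | None = None,
) -> dict[int, dict[str, set[str]]]:
    """word -> set of miRNA ids sharing it, per word length.

    miRNA families often share one seed (e.g. one word serving let-7a
    through let-7i); ``explicit`` entries per k are merged on top of the
    derived words to mirror externally curated family groupings.
    """
    out: dict[int, dict[str, set[str]]] = {}
    for k in ks:
        words: dict[str, set[str]] = {}
        for mirna_id, seq in mature_sequences.items():
            word = derive_seed_words(seq, k)
            words.setdefault(word, set()).add(mirna_id)
        if explicit and k in explicit:
            for word, ids in explicit[k].items():
                words.setdefault(word, set()).update(ids)
        out[k] = words
    return out


def count_word_occurrences(utr_sequence: str, word: str) -> int:
    """Overlapping exact occurrences of ``word`` on the given strand."""
    seq = _to_dna(utr_sequence)
    w = len(word)
    if w == 0 or w > len(seq):
        return 0
    count = 0
    pos = seq.find(word)
    while pos != -1:
        count += 1
        pos = seq.find(word, pos + 1)
    return count


def count_words_in_utrs(
    utrs: dict[str, str], words: set[str], k: int
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene occurrence counts for many same-length words in one pass.

    Returns ``(counts, positions)`` where ``counts`` is a gene x word
    DataFrame of occurrence counts and ``positions`` the number of k-mer
    positions per gene (len - k + 1, floored at 0).
    """
    if any(len(w) != k for w in words):
        raise ValueError("all words must have length k")
    genes = list(utrs)
    word_list = sorted(words)
    col = {w: j for j, w in enumerate(word_list)}
    mat = np.zeros((len(genes), len(word_list)), dtype=np.int64)
    npos = np.zeros(len(genes), dtype=np.int64)
    for i, g in enumerate(genes):
        seq = _to_dna(utrs[g])
        n = len(seq) - k + 1
        npos[i] = max(n, 0)
        for p in range(max(n, 0)):
            j = col.get(seq[p : p + k])
            if j is not None:
                mat[i, j] += 1
    counts = pd.DataFrame(mat, index=genes, columns=word_list)
    return counts, pd.Series(npos, index=genes, name="kmer_positions")


@dataclass
class RankedGeneList:
    """Gene ids ordered most-up-in-A first, with the ranking statistic."""

    gene_ids: list[str]
    score: pd.Series  # mean expression difference, index = gene ids
    comparison: str = ""

    def __post_init__(self):
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in ranking")

    def reversed(self) -> "RankedGeneList":
        return RankedGeneList(list(self.gene_ids[::-1]), -self.score, self.comparison)


def rank_genes(
    mrna_means: pd.DataFrame,
    cell_type_a: str,
    cell_type_b: str,
    utrs: dict[str, str] | None = None,
    min_utr_length: int = 8,
) -> RankedGeneList:
    """Rank genes by mean difference (A - B), most up-regulated in A first.

    Ties break by gene id; genes with a missing or too-short UTR are
    dropped with a log entry when ``utrs`` is given.
    """
    diff = mrna_means[cell_type_a] - mrna_means[cell_type_b]
    if utrs is not None:
        ok = [g for g in diff.index if len(utrs.get(g, "")) >= min_utr_length]
        dropped = len(diff) - len(ok)
        if dropped:
            log.info("dropping %d genes without usable UTRs", dropped)
        diff = diff.loc[ok]
    order = sorted(diff.index, key=lambda g: (-diff[g], g))
    return RankedGeneList(order, diff.loc[order], comparison=f"{cell_type_a}-{cell_type_b}")


@dataclass
class EnrichmentLandscape:
    """Signed -log10 hypergeometric landscape for one word on one ranking."""

    word: str
    comparison: str
    cutpoints: np.ndarray  # leading-window sizes (gene counts)
    values: np.ndarray  # signed -log10 p per cutpoint
    peak_index: int
    peak_p: float
    flat: bool = False  # word absent from every UTR
    k: int = field(init=False)

    def __post_init__(self):
        self.k = len(self.word)

    @property
    def peak_cutpoint(self) -> int:
        return int(self.cutpoints[self.peak_index])

    @property
    def peak_value(self) -> float:
        return float(self.values[self.peak_index])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutpoint": self.cutpoints, "value": self.values})


def _signed_landscape_values(
    obs: np.ndarray, sample: np.ndarray, total_occ: int, total_pos: int
) -> np.ndarray:
    """Signed -log10 of the smaller hypergeometric tail, per cutpoint."""
    # upper tail P(X >= obs), lower tail P(X <= obs)
    p_enr = hypergeom.sf(obs - 1, total_pos, total_occ, sample)
    p_dep = hypergeom.cdf(obs, total_pos, total_occ, sample)
    p_enr = np.clip(p_enr, 1e-320, 1.0)
    p_dep = np.clip(p_dep, 1e-320, 1.0)
    vals = np.where(p_enr <= p_dep, -np.log10(p_enr), np.log10(p_dep))
    return vals


def hypergeometric_landscape(
    ranked_list: RankedGeneList,
    word: str,
    utr_counts: pd.Series,
    utr_positions: pd.Series,
    n_bins: int = 50,
) -> EnrichmentLandscape:
    """Hypergeometric word-enrichment landscape over leading windows.

    ``utr_counts`` holds the word's occurrence count per gene and
    ``utr_positions`` the k-mer position count per gene (the counting
    universe).  For cutpoint i (i = 1..n_bins) the leading window is the
    first ceil(i*N/n_bins) genes; the window's occurrences are tested
    against the full-list totals with both hypergeometric tails, and the signed
    value is -log10 of the smaller tail (positive = enrichment in the
    leading window).  The peak is the cutpoint of largest |value|.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    genes = ranked_list.gene_ids
    occ = utr_counts.reindex(genes).fillna(0).to_numpy(np.int64)
    pos = utr_positions.reindex(genes).fillna(0).to_numpy(np.int64)
    n_genes = len(genes)
    cut_sizes = np.unique(np.ceil(np.arange(1, n_bins + 1) * n_genes / n_bins).astype(int))
    cum_occ = np.cumsum(occ)
    cum_pos = np.cumsum(pos)
    total_occ = int(cum_occ[-1])
    total_pos = int(cum_pos[-1])
    if total_occ == 0:
        vals = np.zeros(len(cut_sizes))
        return EnrichmentLandscape(
            word, ranked_list.comparison, cut_sizes, vals, peak_index=0, peak_p=1.0, flat=True
        )
    obs = cum_occ[cut_sizes - 1]
    sample = cum_pos[cut_sizes - 1]
    vals = _signed_landscape_values(obs, sample, total_occ, total_pos)
    peak = int(np.argmax(np.abs(vals)))
    peak_p = float(10.0 ** (-abs(vals[peak])))
    return EnrichmentLandscape(
        word, ranked_list.comparison, cut_sizes, vals, peak_index=peak, peak_p=peak_p
    )


def landscape_grid(
    ranked_list: RankedGeneList,
    words: set[str],
    utrs: dict[str, str],
    k: int,
    n_bins: int = 50,
) -> dict[str, EnrichmentLandscape]:
    """Landscapes for every word of one length on one ranked list."""
    counts, positions = count_words_in_utrs(utrs, words, k)
    return {
        w: hypergeometric_landscape(ranked_list, w, counts[w], positions, n_bins=n_bins)
        for w in sorted(words)
    }


def genes_under_peak(
    ranked_list: RankedGeneList,
    landscape: EnrichmentLandscape,
    utr_counts: pd.Series,
    p_cutoff: float = 1e-4,
) -> set[str]:
    """Word-containing genes on the enriched side of the landscape peak.

    A positive peak means the word is enriched in the leading window, so
    the window's word-containing genes are returned; a negative peak means
    enrichment beyond the cutpoint, so the trailing genes are used.  A
    non-significant peak returns the empty set.
    """
    if landscape.flat or landscape.peak_p > p_cutoff:
        return set()
    cut = landscape.peak_cutpoint
    if landscape.peak_value >= 0:
        window = ranked_list.gene_ids[:cut]
    else:
        window = ranked_list.gene_ids[cut:]
    occ = utr_counts.reindex(window).fillna(0)
    return set(occ.index[occ > 0])
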
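"""Synthetic miRNA-array study generator with planted ground truth.

Emulates the design the analysis chain assumes: a panel of endothelial-style
cell cultures, each RNA sample hybridized in duplicate, log2 intensities with
feature-specific noise; polycistronic genomic clusters whose members share
cell-type effects; a planted trio of variable miRNAs elevated in a subset of
cell types; and an mRNA compendium in which genes carrying a trio member's
seed word in their 3'UTR are repressed wherever that miRNA is high.  The
planted parameters come back as a :class:`SyntheticTruth` so recovery can be
scored exactly.

Three independent RNG streams (annotation, arrays, UTRs) are derived from the
master seed, so regenerating one artifact leaves the others untouched.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clusters import MirnaLocus
from .expression import ExpressionMatrix
from .seedscan import derive_seed_words

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_mirna_annotation",
    "generate_mirna_matrix",
    "generate_utrs_and_mrna",
    "generate_dataset",
]

# default panel mirrors a 7-culture endothelial design
_DEFAULT_CELL_TYPES = ("HUVEC", "HAEC", "HCEC", "HPAEC", "HPMVEC", "HDMVEC", "HBMVEC")
_BASES = np.array(list("ACGT"))
_MAX_SEED_WORD = 8


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    n_cell_types: int = 7
    n_duplicates_per_sample: int = 2
    n_mirnas: int = 200
    n_clusters: int = 20
    cluster_size_range: tuple[int, int] = (2, 5)
    intra_cluster_gap_bp: int = 2_000
    chrom_length_bp: int = 50_000_000
    locus_length_bp: int = 80
    baseline_mean: float = 7.0
    abundance_spread: float = 4.0  # per-feature abundance ~ U(baseline, baseline+spread)
    trio_abundance_spread: float = 2.0  # trio kept mid-range so normalization cannot saturate
    background_fraction: float = 0.25  # low-intensity miRNAs below the expressed call
    background_mean: float = 4.0
    background_spread: float = 0.75  # background abundance ~ U(mean-spread, mean+spread)
    noise_sd: float = 0.10
    cluster_effect_sd: float = 0.02
    trio_effect_size: float = 1.0  # log2; ~2-fold, the observed scale of the trio
    n_affected_cell_types: int = 3
    n_genes: int = 2_000
    utr_length_range: tuple[int, int] = (200, 800)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    target_fraction: float = 0.15
    repression_effect: float = 1.0  # log2 drop per unit of miRNA excess
    n_probes_per_mirna: int = 1
    probe_effect_sd: float = 0.3
    max_rejection_tries: int = 500
    rng_seed: int = 0
    cell_type_labels: tuple[str, ...] | None = None

    def validate(self) -> None:
        counts = dict(
            n_cell_types=self.n_cell_types,
            n_duplicates_per_sample=self.n_duplicates_per_sample,
            n_mirnas=self.n_mirnas,
            n_clusters=self.n_clusters,
            n_genes=self.n_genes,
            n_probes_per_mirna=self.n_probes_per_mirna,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0 (got {v})")
        lo, hi = self.cluster_size_range
        if not (0 < lo <= hi):
            raise ValueError("cluster_size_range must satisfy 0 < min <= max")
        if self.n_mirnas < self.n_clusters * lo + 3:
            raise ValueError("n_mirnas too small for the requested clusters plus a trio")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.size != 4 or (comp < 0).any() or (comp > 1).any():
            raise ValueError("base_composition must be 4 probabilities in [0,1]")
        if abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1 within 1e-9")
        if self.utr_length_range[0] < _MAX_SEED_WORD:
            raise ValueError(f"minimum UTR length must be >= {_MAX_SEED_WORD}")
        if self.utr_length_range[0] > self.utr_length_range[1]:
            raise ValueError("utr_length_range min > max")
        if not 0 < self.n_affected_cell_types <= self.n_cell_types:
            raise ValueError("n_affected_cell_types outside 1..n_cell_types")
        if not 0 <= self.target_fraction <= 1:
            raise ValueError("target_fraction outside [0,1]")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction outside [0,1)")
        if self.intra_cluster_gap_bp <= 0:
            raise ValueError("intra_cluster_gap_bp must be > 0")

    @property
    def cell_types(self) -> list[str]:
        if self.cell_type_labels is not None:
            labels = list(self.cell_type_labels)
            if len(labels) != self.n_cell_types:
                raise ValueError("cell_type_labels length != n_cell_types")
            return labels
        labels = list(_DEFAULT_CELL_TYPES[: self.n_cell_types])
        labels += [f"CT{i}" for i in range(len(labels) + 1, self.n_cell_types + 1)]
        return labels

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one artifact (annotation=1, arrays=2, UTRs=3)."""
        return np.random.default_rng([int(self.rng_seed), int(stream)])


@dataclass
class SyntheticTruth:
    """Planted parameters needed to score recovery."""

    variable_trio: list[str]
    cluster_assignments: dict[str, str]  # miRNA id -> cluster id (singletons: own id)
    cell_type_effects: dict[str, dict[str, float]]  # cluster id -> cell type -> log2 shift
    trio_affected: dict[str, list[str]]  # trio miRNA -> elevated cell types
    planted_targets: dict[str, list[str]]  # trio miRNA -> target gene ids
    seed_words: dict[str, dict[int, str]]  # miRNA -> k -> word
    expressed_mirnas: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["seed_words"] = {
            m: {str(k): w for k, w in kw.items()} for m, kw in self.seed_words.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        payload["seed_words"] = {
            m: {int(k): w for k, w in kw.items()} for m, kw in payload["seed_words"].items()
        }
        return cls(**payload)


# ---------------------------------------------------------------------
# annotation


def _random_mature(rng: np.random.Generator, comp: np.ndarray) -> str:
    seq = "".join(rng.choice(_BASES, size=22, p=comp))
    return seq.replace("T", "U")


def generate_mirna_annotation(
    config: SyntheticConfig,
) -> tuple[list[MirnaLocus], dict[str, str], SyntheticTruth]:
    """Place clustered and singleton miRNA loci and draw mature sequences.

    Within-cluster neighbours sit exactly ``intra_cluster_gap_bp`` apart;
    consecutive clusters (and singletons) are separated by ten times that,
    so cluster detection at any threshold between the two recovers the
    planted partition.  Mature sequences are 22 nt with mutually distinct
    5' 8-mers, giving every miRNA an unambiguous seed word.
    """
    config.validate()
    rng = config.rng(1)
    lo, hi = config.cluster_size_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_clusters)]
    while sum(sizes) > config.n_mirnas:  # shrink the largest clusters to fit
        if max(sizes) <= lo:
            raise ValueError("n_mirnas too small for requested cluster sizes")
        sizes[sizes.index(max(sizes))] -= 1
    n_singletons = config.n_mirnas - sum(sizes)

    mirna_ids = [f"miR-{i + 1:03d}" for i in range(config.n_mirnas)]
    loci: list[MirnaLocus] = []
    assignments: dict[str, str] = {}
    pos = 10_000
    idx = 0
    between_gap = 10 * config.intra_cluster_gap_bp
    blocks = [sizes[i] for i in range(config.n_clusters)] + [1] * n_singletons
    for block_size in blocks:
        cluster_head = mirna_ids[idx]
        for j in range(block_size):
            mid = mirna_ids[idx]
            end = pos + config.locus_length_bp
            if end > config.chrom_length_bp:
                raise ValueError("chromosome too short for requested locus counts")
            loci.append(MirnaLocus(mid, "chrS", pos, end, "+"))
            assignments[mid] = cluster_head
            idx += 1
            pos = end + (config.intra_cluster_gap_bp if j < block_size - 1 else between_gap)

    comp = np.asarray(config.base_composition, dtype=float)
    matures: dict[str, str] = {}
    seen_heads: set[str] = set()
    for mid in mirna_ids:
        for _ in range(config.max_rejection_tries):
            seq = _random_mature(rng, comp)
            if seq[:8] not in seen_heads:
                seen_heads.add(seq[:8])
                matures[mid] = seq
                break
        else:
            raise ValueError("could not draw mature sequences with distinct 5' 8-mers")

    # trio: one member from each of three distinct multi-miRNA clusters
    multi = [h for h in dict.fromkeys(assignments.values()) if sum(1 for v in assignments.values() if v == h) >= 2]
    if len(multi) >= 3:
        host_clusters = list(rng.choice(np.array(multi, dtype=object), size=3, replace=False))
        trio = []
        for h in host_clusters:
            members = [m for m, c in assignments.items() if c == h]
            trio.append(str(rng.choice(np.array(members, dtype=object))))
    else:
        trio = [str(m) for m in rng.choice(np.array(mirna_ids, dtype=object), size=3, replace=False)]

    cell_types = config.cell_types
    effects: dict[str, dict[str, float]] = {}
    for head in dict.fromkeys(assignments.values()):
        members = [m for m, c in assignments.items() if c == head]
        if len(members) >= 2:
            shifts = rng.normal(0.0, config.cluster_effect_sd, size=len(cell_types))
            effects[head] = {ct: float(s) for ct, s in zip(cell_types, shifts)}
    trio_affected = {
        m: sorted(
            str(ct)
            for ct in rng.choice(
                np.array(cell_types, dtype=object),
                size=config.n_affected_cell_types,
                replace=False,
            )
        )
        for m in trio
    }

    seed_words = {m: {k: derive_seed_words(matures[m], k) for k in (6, 7, 8)} for m in mirna_ids}

    # low-intensity background miRNAs: singletons outside the trio
    singles = [m for m, c in assignments.items() if sum(1 for v in assignments.values() if v == c) == 1]
    eligible = [m for m in singles if m not in trio]
    n_bg = min(int(round(config.background_fraction * config.n_mirnas)), len(eligible))
    background = sorted(str(m) for m in rng.choice(np.array(eligible, dtype=object), size=n_bg, replace=False))
    expressed = [m for m in mirna_ids if m not in set(background)]

    truth = SyntheticTruth(
        variable_trio=sorted(trio),
        cluster_assignments=assignments,
        cell_type_effects=effects,
        trio_affected=trio_affected,
        planted_targets={},
        seed_words=seed_words,
        expressed_mirnas=expressed,
    )
    return loci, matures, truth


# ---------------------------------------------------------------------
# miRNA arrays


def generate_mirna_matrix(
    config: SyntheticConfig, truth: SyntheticTruth
) -> tuple[ExpressionMatrix, ExpressionMatrix | None]:
    """Log2 miRNA intensities: baseline + cluster effect + trio effect + noise.

    Duplicate arrays of one sample share every systematic effect and differ
    only by noise.  Returns ``(summary_matrix, probe_matrix)``; the probe
    matrix (replicate probes per miRNA offset by probe affinities, for
    median-polish summarization) is None when ``n_probes_per_mirna == 1``.
    """
    config.validate()
    rng = config.rng(2)
    cell_types = config.cell_types
    mirnas = sorted(truth.cluster_assignments)
    expressed = set(truth.expressed_mirnas)
    array_ids = [f"{ct}_r{j + 1}" for ct in cell_types for j in range(config.n_duplicates_per_sample)]
    ct_of_array = [ct for ct in cell_types for _ in range(config.n_duplicates_per_sample)]

    # per-feature characteristic abundance: real arrays span many log2 units,
    # and that spread is what lets rank-based normalization preserve shifts
    abundance = {}
    trio = set(truth.variable_trio)
    for m in mirnas:
        if m not in expressed:
            abundance[m] = config.background_mean + float(
                rng.uniform(-config.background_spread, config.background_spread)
            )
        elif m in trio:
            abundance[m] = config.baseline_mean + float(rng.uniform(0.0, config.trio_abundance_spread))
        else:
            abundance[m] = config.baseline_mean + float(rng.uniform(0.0, config.abundance_spread))

    signal = np.zeros((len(mirnas), len(cell_types)))
    for i, m in enumerate(mirnas):
        base = abundance[m]
        cluster = truth.cluster_assignments[m]
        for c, ct in enumerate(cell_types):
            v = base
            v += truth.cell_type_effects.get(cluster, {}).get(ct, 0.0)
            if m in truth.trio_affected and ct in truth.trio_affected[m]:
                v += config.trio_effect_size
            signal[i, c] = v

    col_idx = [cell_types.index(ct) for ct in ct_of_array]
    values = signal[:, col_idx] + rng.normal(0.0, config.noise_sd, (len(mirnas), len(array_ids)))
    summary = ExpressionMatrix(pd.DataFrame(values, index=mirnas, columns=array_ids))

    probe_matrix = None
    if config.n_probes_per_mirna > 1:
        probe_rows = []
        probe_ids = []
        for i, m in enumerate(mirnas):
            affinities = rng.normal(0.0, config.probe_effect_sd, config.n_probes_per_mirna)
            for p, aff in enumerate(affinities):
                noise = rng.normal(0.0, config.noise_sd, len(array_ids))
                probe_rows.append(signal[i, col_idx] + aff + noise)
                probe_ids.append(f"{m}_p{p + 1}")
        probe_matrix = ExpressionMatrix(
            pd.DataFrame(np.array(probe_rows), index=probe_ids, columns=array_ids)
        )
    return summary, probe_matrix


# ---------------------------------------------------------------------
# UTRs and mRNA


def _random_utr(rng: np.random.Generator, length: int, comp: np.ndarray) -> str:
    return "".join(rng.choice(_BASES, size=length, p=comp))


def generate_utrs_and_mrna(
    config: SyntheticConfig, truth: SyntheticTruth
) -> tuple[dict[str, str], ExpressionMatrix]:
    """3'UTR sequences with planted seed sites, plus the mRNA matrix.

    ``target_fraction`` of genes are split round-robin among the trio; each
    target UTR carries 1-3 copies of its miRNA's 8-mer word (so the nested
    7- and 6-mer words as well) and no other trio word.  Non-target UTRs are
    rejection-sampled to contain zero occurrences of any trio 6-mer word,
    which excludes all longer trio words too.  mRNA log2 values are
    baseline - repression_effect * (miRNA excess in the cell type) for
    targets, plus noise; the planted truth gains ``planted_targets``.
    """
    config.validate()
    if not truth.variable_trio:
        raise ValueError("truth lacks a planted trio")
    rng = config.rng(3)
    comp = np.asarray(config.base_composition, dtype=float)
    trio = list(truth.variable_trio)
    # a hit on any longer trio word implies a hit on that trio 6-mer
    forbidden = [truth.seed_words[m][6] for m in trio]
    insert_words = {m: truth.seed_words[m][8] for m in trio}

    gene_ids = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    n_targets = int(round(config.target_fraction * config.n_genes))
    # shuffle which gene ids are targets so rank order carries no artifact
    shuffled = list(rng.permutation(np.array(gene_ids, dtype=object)))
    target_of = {str(shuffled[j]): trio[j % len(trio)] for j in range(n_targets)}

    lo, hi = config.utr_length_range
    utrs: dict[str, str] = {}
    for g in gene_ids:
        length = int(rng.integers(lo, hi + 1))
        for _ in range(config.max_rejection_tries):
            seq = _random_utr(rng, length, comp)
            if any(w in seq for w in forbidden):
                continue
            if g in target_of:
                word = insert_words[target_of[g]]
                n_sites = int(rng.integers(1, 4))
                starts = rng.choice(max(length - 8, 1), size=min(n_sites, max(length // 16, 1)), replace=False)
                chars = list(seq)
                for s in sorted(int(s) for s in starts):
                    chars[s : s + 8] = list(word)
                cand = "".join(chars)
                other = [w for m, w in zip(trio, forbidden) if m != target_of[g]]
                if any(w in cand for w in other):
                    continue
                if word not in cand:  # overlapping writes could mangle a site
                    continue
                seq = cand
            utrs[g] = seq
            break
        else:
            raise ValueError(
                "rejection sampling exceeded retry budget; base composition too "
                "favourable to the planted words"
            )

    planted: dict[str, list[str]] = {m: [] for m in trio}
    for g, m in target_of.items():
        planted[m].append(g)
    truth.planted_targets = {m: sorted(gs) for m, gs in planted.items()}

    cell_types = config.cell_types
    excess = {
        m: {ct: (config.trio_effect_size if ct in truth.trio_affected.get(m, []) else 0.0) for ct in cell_types}
        for m in trio
    }
    array_ids = [f"{ct}_r{j + 1}" for ct in cell_types for j in range(config.n_duplicates_per_sample)]
    ct_of_array = [ct for ct in cell_types for _ in range(config.n_duplicates_per_sample)]
    gene_abundance = config.baseline_mean + rng.uniform(0.0, config.abundance_spread, config.n_genes)
    signal = np.tile(gene_abundance[:, None], (1, len(cell_types)))
    for i, g in enumerate(gene_ids):
        m = target_of.get(g)
        if m is not None:
            for c, ct in enumerate(cell_types):
                signal[i, c] -= config.repression_effect * excess[m][ct]
    col_idx = [cell_types.index(ct) for ct in ct_of_array]
    values = signal[:, col_idx] + rng.normal(0.0, config.noise_sd, (config.n_genes, len(array_ids)))
    mrna = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=array_ids))
    return utrs, mrna


# ---------------------------------------------------------------------
# bundle


@dataclass
class SyntheticDataset:
    """All artifacts of one synthetic study run."""

    config: SyntheticConfig
    truth: SyntheticTruth
    loci: list[MirnaLocus]
    mature_sequences: dict[str, str]
    mirna_matrix: ExpressionMatrix
    probe_matrix: ExpressionMatrix | None
    utrs: dict[str, str]
    mrna_matrix: ExpressionMatrix

    def write(self, outdir) -> dict[str, str]:
        """Write every artifact as plain text; returns name -> path."""
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        p = out / "mirna_matrix.tsv"
        self.mirna_matrix.to_tsv(p, comment="synthetic miRNA log2 matrix")
        paths["mirna_matrix"] = str(p)
        if self.probe_matrix is not None:
            p = out / "mirna_probe_matrix.tsv"
            self.probe_matrix.to_tsv(p, comment="synthetic miRNA probe-level log2 matrix")
            paths["probe_matrix"] = str(p)
            p = out / "probe_map.tsv"
            with open(p, "w") as fh:
                for probe in self.probe_matrix.values.index:
                    fh.write(f"{probe}\t{probe.rsplit('_p', 1)[0]}\n")
            paths["probe_map"] = str(p)
        p = out / "mrna_matrix.tsv"
        self.mrna_matrix.to_tsv(p, comment="synthetic mRNA log2 matrix")
        paths["mrna_matrix"] = str(p)

        p = out / "mirna_loci.bed"
        with open(p, "w") as fh:
            for locus in self.loci:
                fh.write(
                    f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.mirna_id}\t0\t{locus.strand}\n"
                )
        paths["loci"] = str(p)

        p = out / "mature_mirnas.fa"
        SeqIO.write(
            [SeqRecord(Seq(seq), id=mid, description="") for mid, seq in sorted(self.mature_sequences.items())],
            str(p),
            "fasta",
        )
        paths["mature"] = str(p)
        p = out / "utrs.fa"
        SeqIO.write(
            [SeqRecord(Seq(seq), id=g, description="") for g, seq in sorted(self.utrs.items())],
            str(p),
            "fasta",
        )
        paths["utrs"] = str(p)

        p = out / "truth.json"
        self.truth.to_json(p)
        paths["truth"] = str(p)
        return paths


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Run the three generation stages under one config."""
    config = config or SyntheticConfig()
    loci, matures, truth = generate_mirna_annotation(config)
    mirna_matrix, probe_matrix = generate_mirna_matrix(config, truth)
    utrs, mrna = generate_utrs_and_mrna(config, truth)
    return SyntheticDataset(config, truth, loci, matures, mirna_matrix, probe_matrix, utrs, mrna)
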
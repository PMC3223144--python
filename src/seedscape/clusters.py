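"""Polycistronic miRNA chromosomal clusters and cluster-level Z tests.

Genomically adjacent miRNAs are chained into clusters whenever each
consecutive inter-locus gap is at or below a threshold (default 10 kb,
the miRBase-style cluster definition).  Cluster-level differential
expression between two cell types combines the members' signed normal
scores with Stouffer's method, Z = sum(z_i) / sqrt(m), and a follow-up
test drops individually significant members to ask whether the remaining
members still move together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import ModeratedTResults, benjamini_hochberg

log = logging.getLogger(__name__)

__all__ = [
    "MirnaLocus",
    "GenomicCluster",
    "ClusterTestResult",
    "read_loci_bed",
    "read_loci_gff3",
    "detect_clusters",
    "cluster_z_test",
    "retest_without_significant",
    "cluster_test_table",
]


@dataclass(frozen=True)
class MirnaLocus:
    """One miRNA gene locus, 0-based half-open coordinates."""

    mirna_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"{self.mirna_id}: end < start")


@dataclass
class GenomicCluster:
    """A maximal chain of miRNA loci with bounded inter-locus gaps.

    Named after its first (leftmost) member, the convention used for
    polycistrons like the miR-99b or miR-17~92 clusters.
    """

    cluster_id: str
    chrom: str
    members: list[MirnaLocus] = field(default_factory=list)

    @property
    def member_ids(self) -> list[str]:
        return [m.mirna_id for m in self.members]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterTestResult:
    """Stouffer combination of member-level evidence for one comparison."""

    cluster_id: str
    comparison: str
    z_score: float | None
    p_value: float | None
    adj_p_value: float | None
    member_z: dict[str, float]
    members_removed: list[str] = field(default_factory=list)
    fully_driven_by_individuals: bool = False


def read_loci_bed(path) -> list[MirnaLocus]:
    """Read miRNA loci from 6-column BED (0-based half-open)."""
    loci = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 else "."
            loci.append(MirnaLocus(f[3], f[0], int(f[1]), int(f[2]), strand))
    return loci


def read_loci_gff3(path, id_attribute: str = "Name") -> list[MirnaLocus]:
    """Read miRNA loci from GFF3 (1-based inclusive -> 0-based half-open)."""
    loci = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get(id_attribute) or attrs.get("ID")
            loci.append(MirnaLocus(name, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return loci


def detect_clusters(
    loci: list[MirnaLocus],
    gap_threshold_bp: int = 10_000,
    same_strand_only: bool = False,
) -> list[GenomicCluster]:
    """Single-linkage chaining of loci along each chromosome.

    Consecutive loci (sorted by start) join one cluster iff
    ``next.start - prev.end <= gap_threshold_bp``; singletons come back as
    size-1 clusters.  Strand is ignored unless ``same_strand_only``, in
    which case chains are built per strand (true polycistrons are
    co-stranded).
    """
    if gap_threshold_bp <= 0:
        raise ValueError("gap_threshold_bp must be > 0")
    clusters: list[GenomicCluster] = []
    keyfn = (lambda l: (l.chrom, l.strand)) if same_strand_only else (lambda l: l.chrom)
    groups: dict = {}
    for locus in loci:
        groups.setdefault(keyfn(locus), []).append(locus)
    for key in sorted(groups, key=str):
        chain = sorted(groups[key], key=lambda l: (l.start, l.end, l.mirna_id))
        current = [chain[0]]
        for locus in chain[1:]:
            prev_end = max(m.end for m in current)
            if locus.start - prev_end <= gap_threshold_bp:
                current.append(locus)
            else:
                clusters.append(_make_cluster(current))
                current = [locus]
        clusters.append(_make_cluster(current))
    return clusters


def _make_cluster(members: list[MirnaLocus]) -> GenomicCluster:
    return GenomicCluster(members[0].mirna_id, members[0].chrom, list(members))


def _signed_z(p: float, logfc: float) -> float:
    # cap to keep Phi^-1 finite for p ~ 0
    p = min(max(p, 1e-300), 1.0)
    z = stats.norm.isf(p / 2.0)
    return float(np.sign(logfc) * z) if logfc != 0 else 0.0


def cluster_z_test(
    cluster: GenomicCluster,
    results: ModeratedTResults,
    comparison: str | None = None,
    exclude: set[str] | None = None,
) -> ClusterTestResult:
    """Stouffer-combined cluster test from member-level moderated-t results.

    Member z_i = Phi^-1(1 - p_i/2) * sign(logFC_i); Z = sum(z_i)/sqrt(m);
    two-sided p from the standard normal.  Members missing from the results
    (e.g. not expressed, or homolog-confounded ids on an exclusion list)
    are skipped with a log entry.
    """
    exclude = exclude or set()
    comparison = comparison or f"{results.group_a}-{results.group_b}"
    member_z: dict[str, float] = {}
    for mid in cluster.member_ids:
        if mid in exclude:
            log.info("cluster %s: member %s excluded by config", cluster.cluster_id, mid)
            continue
        if mid not in results.table.index:
            log.info("cluster %s: member %s missing from results", cluster.cluster_id, mid)
            continue
        row = results.table.loc[mid]
        member_z[mid] = _signed_z(float(row["pvalue"]), float(row["logFC"]))
    if not member_z:
        raise ValueError(f"cluster {cluster.cluster_id}: no members with test results")
    zs = np.array(list(member_z.values()))
    z_comb = float(zs.sum() / np.sqrt(zs.size))
    p = float(2.0 * stats.norm.sf(abs(z_comb)))
    return ClusterTestResult(
        cluster_id=cluster.cluster_id,
        comparison=comparison,
        z_score=z_comb,
        p_value=p,
        adj_p_value=None,
        member_z=member_z,
    )


def retest_without_significant(
    cluster: GenomicCluster,
    results: ModeratedTResults,
    alpha: float = 0.05,
    comparison: str | None = None,
    exclude: set[str] | None = None,
) -> ClusterTestResult:
    """Re-run the cluster test on members not individually significant.

    Members with unadjusted p < alpha are removed; if none survive the
    result is flagged as fully driven by its individual members.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    comparison = comparison or f"{results.group_a}-{results.group_b}"
    removed = [
        mid
        for mid in cluster.member_ids
        if mid in results.table.index and float(results.table.loc[mid, "pvalue"]) < alpha
    ]
    kept = [m for m in cluster.members if m.mirna_id not in set(removed)]
    kept = [m for m in kept if m.mirna_id in results.table.index and m.mirna_id not in (exclude or set())]
    if not kept:
        return ClusterTestResult(
            cluster_id=cluster.cluster_id,
            comparison=comparison,
            z_score=None,
            p_value=None,
            adj_p_value=None,
            member_z={},
            members_removed=removed,
            fully_driven_by_individuals=True,
        )
    sub = GenomicCluster(cluster.cluster_id, cluster.chrom, kept)
    res = cluster_z_test(sub, results, comparison=comparison, exclude=exclude)
    res.members_removed = removed
    return res


def cluster_test_table(
    clusters: list[GenomicCluster],
    pairwise_results: dict[str, ModeratedTResults],
    min_cluster_size: int = 2,
    adjust: str = "bh",
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """All (cluster x comparison) Stouffer tests with family-wide adjustment.

    Returns a tidy table (Cluster, Comparison, Z.score, P.value, Adj.P.value)
    mirroring the shape of a cluster-level differential-expression report;
    adjustment is BH by default, Bonferroni with ``adjust="bonferroni"``.
    """
    rows = []
    for cluster in clusters:
        if cluster.size < min_cluster_size:
            continue
        for comparison, res in pairwise_results.items():
            try:
                r = cluster_z_test(cluster, res, comparison=comparison, exclude=exclude)
            except ValueError:
                continue
            rows.append((r.cluster_id, r.comparison, r.z_score, r.p_value))
    df = pd.DataFrame(rows, columns=["Cluster", "Comparison", "Z.score", "P.value"])
    if len(df):
        if adjust == "bh":
            df["Adj.P.value"] = benjamini_hochberg(df["P.value"].to_numpy())
        elif adjust == "bonferroni":
            df["Adj.P.value"] = np.minimum(df["P.value"].to_numpy() * len(df), 1.0)
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
    else:
        df["Adj.P.value"] = []
    return df
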
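"""Pairwise empirical-Bayes moderated-t differential expression.

The model shrinks each feature's residual variance s_g^2 (d_g degrees of
freedom) toward a common prior s0^2 with d0 prior degrees of freedom,

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and refers t~ = logFC / (s~_g * sqrt(1/n_a + 1/n_b)) to a t distribution on
d0 + d_g df.  The hyperparameters (d0, s0^2) are estimated by matching the
first two moments of log s_g^2 to a scaled log-F distribution via the
digamma/trigamma equations.  Also here: BH adjustment, Pearson-correlation
average-linkage clustering of sample profiles, and the three-way Venn
partition of significance patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list, to_tree
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ModeratedT",
    "ModeratedTResults",
    "moderated_t_pairwise",
    "fit_variance_prior",
    "benjamini_hochberg",
    "pearson_cluster",
    "venn_partition",
]


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is strictly decreasing; iteration in 1/x space is stable
    (cf. the standard approach in empirical-Bayes variance moderation).
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match log s^2 to a scaled log-F; return (d0, s0_squared).

    With z = log s_g^2, E[z] = log s0^2 + digamma(d_g/2) - log(d_g/2)
    + (log s0^2 terms of the prior): the centered values
    e_g = z - digamma(d_g/2) + log(d_g/2) have mean log s0^2 - digamma(d0/2)
    + log(d0/2)... solved via mean/variance of e_g.  Returns d0 = inf when
    the observed spread of log variances is no larger than sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.any(s2 < 0):
        raise ValueError("negative variances")
    if np.any(df <= 0):
        raise ValueError("zero residual degrees of freedom")
    eps = np.finfo(float).tiny
    z = np.log(np.maximum(s2, eps))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    if n < 2:
        return np.inf, float(s2.mean())
    evar = e.var(ddof=1) - _trigamma(df / 2.0).mean()
    if evar <= 0:
        # no excess spread in the log variances: infinite prior df, and the
        # prior variance is the plain average (no log-scale bias correction),
        # so identical variances shrink to themselves
        return np.inf, float(s2.mean())
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


@dataclass
class ModeratedTResults:
    """Fitted moderated-t results for one two-group contrast."""

    table: pd.DataFrame  # feature, logFC, s2, df, s2_post, t, df_total, pvalue, adj_pvalue
    d0: float
    s0_squared: float
    group_a: str
    group_b: str
    n_a: int
    n_b: int

    @property
    def pvalues(self) -> pd.Series:
        return self.table["pvalue"]

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> set[str]:
        col = "adj_pvalue" if adjusted else "pvalue"
        return set(self.table.index[self.table[col] < alpha])

    def summary(self, n: int = 10) -> str:
        head = self.table.sort_values("pvalue").head(n)
        lines = [
            f"Moderated t contrast: {self.group_a} vs {self.group_b} "
            f"(n={self.n_a}+{self.n_b} arrays, {len(self.table)} features)",
            f"prior df d0 = {self.d0:.4g}, prior variance s0^2 = {self.s0_squared:.4g}",
            f"top {len(head)} features by p-value:",
            head.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


class ModeratedT:
    """Two-group empirical-Bayes moderated t model on an expression matrix.

    Groups are cell-type labels; duplicate arrays of one sample are treated
    as independent replicates within the group unless ``average_duplicates``
    collapses them to per-sample means first.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        cell_type_a: str,
        cell_type_b: str,
        average_duplicates: bool = False,
    ) -> None:
        self.matrix = matrix
        self.cell_type_a = cell_type_a
        self.cell_type_b = cell_type_b

        def _group_values(ct: str) -> np.ndarray:
            arrays = matrix.arrays_of_cell_type(ct)
            if not arrays:
                raise ValueError(f"no arrays for cell type {ct!r}")
            vals = matrix.values[arrays]
            if average_duplicates:
                samples = [matrix.sample_of_array[a] for a in arrays]
                vals = vals.T.groupby(pd.Index(samples, name="sample")).mean().T
            return vals.to_numpy(float)

        self._xa = _group_values(cell_type_a)
        self._xb = _group_values(cell_type_b)
        if self._xa.shape[1] < 2 or self._xb.shape[1] < 2:
            raise ValueError("each group needs >= 2 arrays (or samples)")

    def fit(self) -> ModeratedTResults:
        xa, xb = self._xa, self._xb
        na, nb = xa.shape[1], xb.shape[1]
        df_resid = na + nb - 2
        mean_a = xa.mean(axis=1)
        mean_b = xb.mean(axis=1)
        logfc = mean_a - mean_b
        rss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
        s2 = rss / df_resid
        dfs = np.full_like(s2, float(df_resid))
        d0, s0_sq = fit_variance_prior(s2, dfs)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.full_like(s2, np.inf)
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = np.full_like(s2, d0 + df_resid)
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, logfc / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p = np.clip(p, 0.0, 1.0)
        table = pd.DataFrame(
            {
                "logFC": logfc,
                "s2": s2,
                "df": dfs,
                "s2_post": s2_post,
                "t": t,
                "df_total": df_total,
                "pvalue": p,
                "adj_pvalue": benjamini_hochberg(p),
            },
            index=self.matrix.values.index,
        )
        return ModeratedTResults(
            table=table,
            d0=float(d0),
            s0_squared=float(s0_sq),
            group_a=self.cell_type_a,
            group_b=self.cell_type_b,
            n_a=na,
            n_b=nb,
        )


def moderated_t_pairwise(
    matrix: ExpressionMatrix, cell_type_a: str, cell_type_b: str, **kwargs
) -> ModeratedTResults:
    """Convenience wrapper: build and fit :class:`ModeratedT`."""
    return ModeratedT(matrix, cell_type_a, cell_type_b, **kwargs).fit()


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------
# correlation clustering


def pearson_cluster(matrix: ExpressionMatrix, feature_subset=None):
    """Average-linkage clustering of sample profiles, distance 1 - Pearson r.

    Returns ``(linkage, ordered_values, leaf_order)`` where ``linkage`` is a
    scipy linkage matrix over the arrays, ``ordered_values`` is the feature x
    array matrix with columns in dendrogram leaf order, and ``leaf_order``
    the array ids in that order.  Zero-variance features are dropped with a
    log entry because their correlations are undefined.
    """
    sub = matrix.values
    if feature_subset is not None:
        feature_subset = list(feature_subset)
        if not feature_subset:
            raise ValueError("empty feature subset")
        sub = sub.loc[feature_subset]
    keep = sub.std(axis=1, ddof=0) > 0
    if (~keep).any():
        log.warning("dropping %d zero-variance features from clustering", int((~keep).sum()))
    sub = sub.loc[keep]
    if sub.shape[0] == 0:
        raise ValueError("no features with variance left to cluster")
    if sub.shape[1] < 3:
        raise ValueError("clustering needs >= 3 samples")
    corr = np.corrcoef(sub.to_numpy(float).T)
    dist = 1.0 - corr
    n = dist.shape[0]
    iu = np.triu_indices(n, k=1)
    condensed = np.maximum(dist[iu], 0.0)
    linkage = average(condensed)
    order = _deterministic_leaf_order(linkage, list(sub.columns))
    idx = [list(sub.columns).index(a) for a in order]
    return linkage, sub.iloc[:, idx], order


def _deterministic_leaf_order(linkage: np.ndarray, labels: list[str]) -> list[str]:
    """Leaf order with ties broken by smallest label in each subtree."""
    tree = to_tree(linkage)

    def walk(node):
        if node.is_leaf():
            return [labels[node.id]], labels[node.id]
        left, lmin = walk(node.left)
        right, rmin = walk(node.right)
        if rmin < lmin:
            left, right, lmin = right, left, rmin
        return left + right, lmin

    order, _ = walk(tree)
    return order


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix to a Newick string with branch lengths."""
    tree = to_tree(linkage)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        inner = ",".join(walk(c, node.dist) for c in (node.left, node.right))
        return f"({inner}):{length:.6g}"

    inner = ",".join(walk(c, tree.dist) for c in (tree.left, tree.right))
    return f"({inner});"


# ---------------------------------------------------------------------
# Venn partition


def venn_partition(results: dict[str, "ModeratedTResults"], alpha: float = 0.05):
    """Partition features by their significance pattern over 3 comparisons.

    ``results`` maps comparison labels (e.g. lineage pairs) to fitted
    moderated-t results over one shared feature universe.  Each feature goes
    to the region named by the sorted labels of the comparisons in which its
    unadjusted p < alpha, or ``"none"``.  Returns ``(assignment, counts)``.
    """
    if len(results) != 3:
        raise ValueError("venn_partition expects exactly 3 comparisons")
    labels = sorted(results)
    universes = [tuple(results[k].table.index) for k in labels]
    if len(set(universes)) != 1:
        raise ValueError("comparisons cover different feature universes")
    assignment: dict[str, str] = {}
    for feat in universes[0]:
        sig = [k for k in labels if results[k].table.loc[feat, "pvalue"] < alpha]
        assignment[feat] = "&".join(sig) if sig else "none"
    counts: dict[str, int] = {}
    for region in assignment.values():
        counts[region] = counts.get(region, 0) + 1
    return assignment, counts
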
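"""Multiclass SAM: permutation-calibrated d statistics with a fudge factor.

The per-feature statistic is d_i = r_i / (s_i + s0), where for K groups of
sizes n_k (N = sum n_k):

    r_i = sqrt( (N / prod(n_k)) * sum_k n_k (xbar_ik - xbar_i)^2 )
    s_i = sqrt( (sum_k 1/n_k) / (sum_k (n_k - 1)) * sum_k sum_j (x - xbar_ik)^2 )

which reduces to the classic two-class SAM statistic at K = 2.  The fudge
factor s0 is the s-quantile that minimizes the coefficient of variation of
the d spread across windows of s (the Tusher/Chu construction).  The null
distribution of d comes from group-label permutations; for each threshold
delta the cutoff is the smallest sorted d whose deviation from the mean
permuted order statistic reaches delta, and

    FDR(delta) = median over permutations of #{null d >= cut} / #{observed d >= cut}.

Because r_i >= 0 for the multiclass statistic, only the upper tail exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = ["SAM", "SAMResults", "sam_multiclass"]


def _multiclass_rs(x: np.ndarray, group_cols: list[np.ndarray]):
    """Between-group contrast r and pooled within-group scale s, per feature."""
    nn = np.array([len(g) for g in group_cols], dtype=float)
    xbar = x.mean(axis=1)
    means = np.stack([x[:, g].mean(axis=1) for g in group_cols], axis=1)
    ss_between = (nn * (means - xbar[:, None]) ** 2).sum(axis=1)
    fac = nn.sum() / np.prod(nn)
    r = np.sqrt(fac * ss_between)
    ss_within = np.zeros(x.shape[0])
    for j, g in enumerate(group_cols):
        ss_within += ((x[:, g] - means[:, [j]]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / nn).sum() / (nn - 1.0).sum() * ss_within)
    return r, s


def _d_statistic(r: np.ndarray, s: np.ndarray, s0: float) -> np.ndarray:
    denom = s + s0
    return np.divide(r, denom, out=np.zeros_like(r), where=denom > 0)


def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor minimizing the coefficient of variation of the d spread.

    Candidates are the 0th..100th (step 5) percentiles of s; for each, the
    features are binned into s-quantile windows and the CV of the per-window
    median absolute deviation of d is computed.
    """
    n = s.size
    # enough windows to measure spread, enough members for a stable MAD
    n_windows = max(2, min(100, n // 25))
    qs = np.percentile(s, np.linspace(0, 100, n_windows + 1))
    window = np.clip(np.searchsorted(qs, s, side="right") - 1, 0, n_windows - 1)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    scored: list[tuple[float, float]] = []
    for s0 in candidates:
        d = _d_statistic(r, s, s0)
        mads = []
        for w in range(n_windows):
            dw = d[window == w]
            if dw.size >= 2:
                mads.append(np.median(np.abs(dw - np.median(dw))) / 0.64)
        mads = np.asarray(mads)
        if mads.size < 2 or np.mean(mads) == 0:
            continue
        scored.append((float(s0), float(np.std(mads, ddof=1) / np.mean(mads))))
    if not scored:
        return float(candidates[0])
    # the CV landscape is often nearly flat; within estimation noise of the
    # minimum, prefer the largest fudge factor (damping small-variance
    # artifacts is conservative, amplifying them is not)
    cv_min = min(cv for _, cv in scored)
    return max(s0 for s0, cv in scored if cv <= 1.05 * cv_min)


def _distinct_label_arrangements(group_sizes: list[int]) -> int:
    total = math.factorial(sum(group_sizes))
    for n in group_sizes:
        total //= math.factorial(n)
    return total


def _enumerate_assignments(group_sizes: list[int]):
    """Yield all distinct assignments of N columns to the labelled groups."""
    import itertools

    def rec(remaining: frozenset, sizes: list[int]):
        if not sizes:
            yield []
            return
        for combo in itertools.combinations(sorted(remaining), sizes[0]):
            rest = remaining.difference(combo)
            for tail in rec(rest, sizes[1:]):
                yield [list(combo)] + tail

    yield from rec(frozenset(range(sum(group_sizes))), list(group_sizes))


@dataclass
class SAMResults:
    """Fitted multiclass SAM results."""

    d: pd.Series
    s0: float
    n_permutations: int
    exhaustive: bool
    delta_table: pd.DataFrame  # delta, n_significant, fdr
    chosen_delta: float | None
    significant: set[str] = field(default_factory=set)
    fdr_level: float = 0.05
    expected_d: np.ndarray | None = None  # mean permuted order statistics

    def summary(self) -> str:
        lines = [
            f"Multiclass SAM over {self.d.size} features, s0 = {self.s0:.4g}, "
            f"{self.n_permutations} {'exhaustive' if self.exhaustive else 'sampled'} permutations",
        ]
        if self.chosen_delta is None:
            lines.append(f"no delta reached FDR <= {self.fdr_level}; no features called")
        else:
            lines.append(
                f"delta = {self.chosen_delta:.4g} (FDR <= {self.fdr_level}): "
                f"{len(self.significant)} significant features"
            )
            lines.append("significant: " + ", ".join(sorted(self.significant)))
        return "\n".join(lines)


class SAM:
    """Multiclass SAM model over the cell-type groups of an expression matrix."""

    def __init__(self, matrix: ExpressionMatrix, min_groups: int = 3) -> None:
        self.matrix = matrix
        cts = matrix.cell_types
        if len(cts) < min_groups:
            raise ValueError(f"SAM multiclass needs >= {min_groups} cell types")
        cols = list(matrix.values.columns)
        self.group_cols = [
            np.array([cols.index(a) for a in matrix.arrays_of_cell_type(ct)]) for ct in cts
        ]
        sizes = [len(g) for g in self.group_cols]
        if min(sizes) < 2:
            raise ValueError("every cell type needs >= 2 arrays")
        self.group_sizes = sizes
        self._x = matrix.values.to_numpy(float)

    def fit(
        self,
        n_permutations: int = 1000,
        delta_grid: np.ndarray | None = None,
        rng_seed: int = 0,
        fdr_level: float = 0.05,
    ) -> SAMResults:
        import warnings

        if n_permutations < 100:
            warnings.warn("fewer than 100 permutations gives unstable FDR estimates")
        x = self._x
        r, s = _multiclass_rs(x, self.group_cols)
        s0 = _choose_s0(r, s)
        d = _d_statistic(r, s, s0)

        total = _distinct_label_arrangements(self.group_sizes)
        exhaustive = total <= n_permutations
        null_sorted = []
        if exhaustive:
            for assignment in _enumerate_assignments(self.group_sizes):
                cols = [np.array(g) for g in assignment]
                rp, sp = _multiclass_rs(x, cols)
                null_sorted.append(np.sort(_d_statistic(rp, sp, s0)))
            n_used = len(null_sorted)
        else:
            rng = np.random.default_rng(rng_seed)
            ncol = x.shape[1]
            for _ in range(n_permutations):
                perm = rng.permutation(ncol)
                cols = []
                off = 0
                for sz in self.group_sizes:
                    cols.append(perm[off : off + sz])
                    off += sz
                rp, sp = _multiclass_rs(x, cols)
                null_sorted.append(np.sort(_d_statistic(rp, sp, s0)))
            n_used = n_permutations
        null_sorted = np.asarray(null_sorted)  # perms x features, each row sorted
        expected = null_sorted.mean(axis=0)

        order = np.argsort(d, kind="stable")
        d_sorted = d[order]
        dev = d_sorted - expected

        if delta_grid is None:
            top = max(dev.max(), 0.0)
            delta_grid = np.linspace(0.0, top, 81)[1:]

        rows = []
        feature_ids = np.asarray(self.matrix.values.index)
        chosen = None
        chosen_sig: set[str] = set()
        for delta in delta_grid:
            hits = np.nonzero(dev >= delta)[0]
            if hits.size == 0:
                rows.append((float(delta), 0, 0.0))
                if chosen is None:
                    chosen = float(delta)
                    chosen_sig = set()
                continue
            cut = d_sorted[hits[0]]
            n_sig = int((d >= cut).sum())
            null_counts = (null_sorted >= cut).sum(axis=1)
            fdr = float(np.median(null_counts)) / n_sig
            rows.append((float(delta), n_sig, fdr))
            if chosen is None and fdr <= fdr_level:
                chosen = float(delta)
                chosen_sig = set(feature_ids[d >= cut])
        delta_table = pd.DataFrame(rows, columns=["delta", "n_significant", "fdr"])

        return SAMResults(
            d=pd.Series(d, index=self.matrix.values.index, name="d"),
            s0=s0,
            n_permutations=n_used,
            exhaustive=exhaustive,
            delta_table=delta_table,
            chosen_delta=chosen,
            significant=chosen_sig,
            fdr_level=fdr_level,
            expected_d=expected,
        )


def sam_multiclass(
    matrix: ExpressionMatrix,
    n_permutations: int = 1000,
    delta_grid: np.ndarray | None = None,
    rng_seed: int = 0,
    fdr_level: float = 0.05,
) -> SAMResults:
    """Convenience wrapper: build and fit :class:`SAM`."""
    return SAM(matrix).fit(
        n_permutations=n_permutations,
        delta_grid=delta_grid,
        rng_seed=rng_seed,
        fdr_level=fdr_level,
    )
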
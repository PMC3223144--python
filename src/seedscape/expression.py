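"""Expression matrices and array preprocessing.

The container here is a thin wrapper around a pandas DataFrame of log2
intensities (features x arrays) that also carries the array -> biological
sample and sample -> cell-type maps needed by the replicate-aware stages
downstream (expressed calls, group contrasts, duplicate averaging).

Preprocessing follows the RMA recipe without background correction:
quantile normalization across arrays followed by median-polish
summarization of replicate probes per feature.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression_tsv",
    "read_probe_map",
    "quantile_normalize",
    "median_polish",
    "median_polish_summarize",
    "call_expressed",
    "delta_delta_ct",
]


def _derive_sample(array_id: str) -> str:
    """Default array -> sample rule: strip a trailing ``_r<k>`` replicate tag."""
    if "_r" in array_id:
        head, _, tail = array_id.rpartition("_r")
        if tail.isdigit():
            return head
    return array_id


def _derive_cell_type(sample_id: str) -> str:
    """Default sample -> cell type rule: text before an optional ``-<n>`` suffix."""
    head, _, tail = sample_id.rpartition("-")
    if tail.isdigit() and head:
        return head
    return sample_id


@dataclass
class ExpressionMatrix:
    """Log2 feature x array matrix with replicate structure.

    Parameters
    ----------
    values
        DataFrame of log2 intensities; index = feature ids, columns = array ids.
    sample_of_array
        Maps each array id to its biological sample id. Duplicate arrays of
        one RNA sample share a sample id.
    cell_type_of_sample
        Maps each sample id to its cell-type label.
    """

    values: pd.DataFrame
    sample_of_array: dict[str, str] = field(default_factory=dict)
    cell_type_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate array ids")
        if not self.sample_of_array:
            self.sample_of_array = {a: _derive_sample(a) for a in self.values.columns}
        if not self.cell_type_of_sample:
            self.cell_type_of_sample = {
                s: _derive_cell_type(s) for s in dict.fromkeys(self.sample_of_array.values())
            }
        missing = [a for a in self.values.columns if a not in self.sample_of_array]
        if missing:
            raise ValueError(f"arrays without a sample mapping: {missing[:5]}")
        missing = [
            s for s in self.sample_of_array.values() if s not in self.cell_type_of_sample
        ]
        if missing:
            raise ValueError(f"samples without a cell type: {missing[:5]}")

    # -- introspection -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    def cell_type_of_array(self, array_id: str) -> str:
        return self.cell_type_of_sample[self.sample_of_array[array_id]]

    @property
    def cell_types(self) -> list[str]:
        """Cell-type labels in first-appearance column order."""
        return list(dict.fromkeys(self.cell_type_of_array(a) for a in self.values.columns))

    def arrays_of_cell_type(self, cell_type: str) -> list[str]:
        return [a for a in self.values.columns if self.cell_type_of_array(a) == cell_type]

    def cell_type_means(self) -> pd.DataFrame:
        """Feature x cell-type matrix of means over each type's arrays."""
        cols = {ct: self.values[self.arrays_of_cell_type(ct)].mean(axis=1) for ct in self.cell_types}
        return pd.DataFrame(cols)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(feature_ids)].copy(),
            dict(self.sample_of_array),
            dict(self.cell_type_of_sample),
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, dict(self.sample_of_array), dict(self.cell_type_of_sample))

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(",".join(self.values.columns).encode())
        h.update(",".join(self.values.index).encode())
        h.update(np.ascontiguousarray(self.values.to_numpy(float)).tobytes())
        return h.hexdigest()[:16]

    # -- IO ------------------------------------------------------------
    def to_tsv(self, path, comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if comment:
                fh.write(f"# {comment}\n")
            self.values.to_csv(fh, sep="\t", index_label="feature_id", float_format="%.17g")


def read_expression_tsv(
    path,
    dialect: str = "plain",
    sample_of_array: dict[str, str] | None = None,
    cell_type_of_sample: dict[str, str] | None = None,
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Read a feature x array TSV table into an :class:`ExpressionMatrix`.

    ``dialect="plain"`` expects a header row of array ids; ``"geo-series-matrix"``
    additionally skips ``!``-prefixed metadata lines and strips quoting, the way
    GEO series-matrix files are written. ``log2_transform`` applies log2 on read
    for linear-scale tables (non-positive values are an error then).
    """
    if dialect not in ("plain", "geo-series-matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if dialect == "geo-series-matrix" and line.startswith("!"):
                continue
            fields = [f.strip('"') for f in line.split("\t")]
            rows.append(fields)
    if not rows:
        raise ValueError(f"no data rows in {path}")
    header = rows[0]
    width = len(header)
    for i, r in enumerate(rows[1:], start=2):
        if len(r) != width:
            raise ValueError(f"ragged row at line {i}: {len(r)} fields, expected {width}")
    ids = [r[0] for r in rows[1:]]
    data = np.array([[float(v) for v in r[1:]] for r in rows[1:]], dtype=float)
    df = pd.DataFrame(data, index=ids, columns=header[1:])
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("duplicate feature or array ids")
    if log2_transform:
        if (df.to_numpy() <= 0).any():
            raise ValueError("non-positive values cannot be log2 transformed")
        df = np.log2(df)
    return ExpressionMatrix(df, sample_of_array or {}, cell_type_of_sample or {})


def read_probe_map(path) -> dict[str, str]:
    """Read a 2-column probe-id -> feature-id TSV (many probes to one feature)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            probe, feat = line.split("\t")[:2]
            if probe in mapping:
                raise ValueError(f"probe {probe!r} mapped twice")
            mapping[probe] = feat
    return mapping


# ---------------------------------------------------------------------
# quantile normalization


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every array onto the common (per-rank cross-array mean) distribution.

    Ties within an array receive the mean of the reference values at their
    tied ranks, so the transform is idempotent.
    """
    x = matrix.values.to_numpy(float)
    if x.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 arrays")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in input")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # average reference values over tied input values
        s = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[:, j] = s
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(df)


# ---------------------------------------------------------------------
# median polish


def median_polish(data: np.ndarray, tol: float = 1e-4, max_iter: int = 10):
    """Tukey median polish of a 2-D array.

    Alternating row/column median sweeps of the additive model
    ``value ~ overall + row + col``; stops when the largest absolute change
    in the residuals over a full sweep drops below ``tol``.

    Returns ``(overall, row_effects, col_effects, residuals)``.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    z = np.asarray(data, dtype=float).copy()
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    for _ in range(max_iter):
        before = z.copy()
        rmed = np.median(z, axis=1)
        z -= rmed[:, None]
        row += rmed
        cdelta = np.median(col)
        col -= cdelta
        overall += cdelta
        cmed = np.median(z, axis=0)
        z -= cmed[None, :]
        col += cmed
        rdelta = np.median(row)
        row -= rdelta
        overall += rdelta
        if np.max(np.abs(z - before)) < tol:
            break
    return overall, row, col, z


def median_polish_summarize(
    probe_matrix: ExpressionMatrix,
    probe_map: dict[str, str],
    tol: float = 1e-4,
    max_iter: int = 10,
) -> ExpressionMatrix:
    """Summarize replicate probes per feature by median polish.

    Per feature the probes x arrays block is fitted with
    ``value ~ overall + probe + array`` and the per-array summary is
    ``overall + array effect``. Single-probe features pass through.
    """
    unmapped = [p for p in probe_matrix.values.index if p not in probe_map]
    if unmapped:
        raise ValueError(f"probes without feature mapping: {unmapped[:5]}")
    groups: dict[str, list[str]] = {}
    for probe in probe_matrix.values.index:
        groups.setdefault(probe_map[probe], []).append(probe)
    rows = {}
    for feat, probes in groups.items():
        block = probe_matrix.values.loc[probes].to_numpy(float)
        if block.shape[0] == 1:
            rows[feat] = block[0]
        else:
            overall, _, coleff, _ = median_polish(block, tol=tol, max_iter=max_iter)
            rows[feat] = overall + coleff
    df = pd.DataFrame.from_dict(rows, orient="index", columns=probe_matrix.values.columns)
    return ExpressionMatrix(df, dict(probe_matrix.sample_of_array), dict(probe_matrix.cell_type_of_sample))


# ---------------------------------------------------------------------
# expressed calls


def call_expressed(
    matrix: ExpressionMatrix, min_mean: float = 6.0, min_celltypes: int = 1
) -> set[str]:
    """Features whose duplicate-mean exceeds ``min_mean`` in enough cell types.

    A feature is called expressed when the mean over the arrays of at least
    ``min_celltypes`` cell types is above ``min_mean`` (log2 scale).
    """
    if not np.isfinite([min_mean]).all():
        raise ValueError("min_mean must be finite")
    cts = matrix.cell_types
    if min_celltypes > len(cts) or min_celltypes < 1:
        raise ValueError(f"min_celltypes={min_celltypes} outside 1..{len(cts)}")
    means = matrix.cell_type_means()
    n_above = (means > min_mean).sum(axis=1)
    return set(means.index[n_above >= min_celltypes])


# ---------------------------------------------------------------------
# qPCR helper


def delta_delta_ct(
    ct_target: float, ct_reference: float, ct_target_cal: float, ct_reference_cal: float
) -> float:
    """Relative expression fold by the delta-delta-Ct rule.

    ``2 ** -((ct_target - ct_reference) - (ct_target_cal - ct_reference_cal))``,
    i.e. the target normalized to a reference transcript (e.g. U6 snRNA) and
    then to a calibrator sample.
    """
    cts = (ct_target, ct_reference, ct_target_cal, ct_reference_cal)
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target - ct_reference) - (ct_target_cal - ct_reference_cal)
    return float(2.0 ** (-ddct))
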
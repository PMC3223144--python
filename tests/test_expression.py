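"""Expression container, TSV IO, and RMA-style preprocessing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seedscape.expression import (
    ExpressionMatrix,
    call_expressed,
    delta_delta_ct,
    median_polish,
    median_polish_summarize,
    quantile_normalize,
    read_expression_tsv,
)

from conftest import make_matrix


# ---------------------------------------------------------------- IO


class TestReadWrite:
    def test_plain_tsv_values(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("feature_id\ta1\ta2\ng1\t1.5\t2.5\ng2\t3\t4\n")
        m = read_expression_tsv(p)
        assert m.feature_ids == ["g1", "g2"]
        assert m.array_ids == ["a1", "a2"]
        assert m.values.to_numpy().tolist() == [[1.5, 2.5], [3.0, 4.0]]

    def test_geo_series_matrix_dialect_skips_metadata(self, tmp_path):
        plain = tmp_path / "plain.tsv"
        plain.write_text("id\ta1\ta2\ng1\t1\t2\ng2\t3\t4\n")
        geo = tmp_path / "geo.tsv"
        geo.write_text(
            '!Series_title\t"demo"\n"id"\t"a1"\t"a2"\n"g1"\t1\t2\n'
            '!Series_end\t1\n"g2"\t3\t4\n'
        )
        a = read_expression_tsv(plain)
        b = read_expression_tsv(geo, dialect="geo-series-matrix")
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_round_trip_is_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(7, 2, (20, 4)), ["A_r1", "A_r2", "B_r1", "B_r2"])
        m.to_tsv(tmp_path / "m.tsv", comment="round trip")
        back = read_expression_tsv(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(m.values, back.values)
        assert back.sample_of_array == m.sample_of_array

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("id\ta1\ta2\ng1\t1\t2\ng2\t3\n")
        with pytest.raises(ValueError, match="ragged"):
            read_expression_tsv(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("id\ta1\ta2\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_expression_tsv(p)

    def test_replicate_structure_derived_from_ids(self):
        m = make_matrix(np.zeros((2, 4)), ["HUVEC_r1", "HUVEC_r2", "HAEC_r1", "HAEC_r2"])
        assert m.sample_of_array["HUVEC_r2"] == "HUVEC"
        assert m.cell_types == ["HUVEC", "HAEC"]
        assert m.arrays_of_cell_type("HAEC") == ["HAEC_r1", "HAEC_r2"]


# ------------------------------------------------- quantile normalization


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        m = make_matrix(np.tile([[1.0], [5.0], [3.0]], (1, 3)), ["a1", "a2", "a3"])
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_hand_computed_rank_means(self):
        m = make_matrix([[1, 2], [2, 4], [3, 6]], ["a1", "a2"])
        out = quantile_normalize(m)
        expected = np.array([[1.5, 1.5], [3.0, 3.0], [4.5, 4.5]])
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_monotone_transform_gives_identical_columns(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        cols = np.stack([base, 2 * base + 1, np.exp(base)], axis=1)
        out = quantile_normalize(make_matrix(cols, ["a1", "a2", "a3"])).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], out[:, 1])
        np.testing.assert_allclose(out[:, 0], out[:, 2])

    def test_ties_get_mean_of_reference_ranks(self):
        m = make_matrix([[1, 1], [1, 2], [3, 3]], ["a1", "a2"])
        out = quantile_normalize(m).values.to_numpy()
        # col a1 ties at 1 occupy ranks 1-2; both get mean(ref[0], ref[1])
        ref = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)
        np.testing.assert_allclose(out[:2, 0], [(ref[0] + ref[1]) / 2] * 2)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.normal(0, 1, (12, 4)), ["a1", "a2", "a3", "a4"])
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12
        )

    def test_nonfinite_rejected(self):
        m = make_matrix([[1, np.nan], [2, 3]], ["a1", "a2"])
        with pytest.raises(ValueError, match="finite"):
            quantile_normalize(m)


# ------------------------------------------------------ median polish


def _median_polish_oracle(data, tol, max_iter):
    """Independent plain-Python median polish with the same sweep order."""

    def med(v):
        s = sorted(v)
        h = len(s) // 2
        return s[h] if len(s) % 2 else 0.5 * (s[h - 1] + s[h])

    z = [[float(v) for v in row] for row in data]
    nr, nc = len(z), len(z[0])
    overall, row, col = 0.0, [0.0] * nr, [0.0] * nc
    for _ in range(max_iter):
        before = [r[:] for r in z]
        for i in range(nr):
            m = med(z[i])
            row[i] += m
            for j in range(nc):
                z[i][j] -= m
        d = med(col)
        overall += d
        for j in range(nc):
            col[j] -= d
        for j in range(nc):
            m = med([z[i][j] for i in range(nr)])
            col[j] += m
            for i in range(nr):
                z[i][j] -= m
        d = med(row)
        overall += d
        for i in range(nr):
            row[i] -= d
        if max(abs(z[i][j] - before[i][j]) for i in range(nr) for j in range(nc)) < tol:
            break
    return overall, row, col, z


class TestMedianPolish:
    def test_exactly_additive_recovered_in_one_sweep(self):
        probe = np.array([1.0, 2.0, 4.0])
        array = np.array([0.0, 3.0, 5.0, 6.0])
        data = probe[:, None] + array[None, :] + 2.0
        overall, row, col, resid = median_polish(data, tol=1e-9, max_iter=10)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)
        # summaries reproduce the additive array values up to the probe offset
        summary = overall + col
        np.testing.assert_allclose(np.diff(summary), np.diff(array + 2.0), atol=1e-12)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        data = rng.normal(8, 1, (4, 5))
        mine = median_polish(data, tol=1e-10, max_iter=200)
        theirs = _median_polish_oracle(data, tol=1e-10, max_iter=200)
        np.testing.assert_allclose(mine[0], theirs[0], atol=1e-8)
        np.testing.assert_allclose(mine[2], theirs[2], atol=1e-8)
        np.testing.assert_allclose(mine[3], np.array(theirs[3]), atol=1e-8)

    def test_absolute_residual_objective_non_increasing(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 1, (6, 7))
        objectives = [
            np.abs(median_polish(data, tol=1e-15, max_iter=k)[3]).sum()
            for k in (1, 2, 3, 5, 10)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(objectives, objectives[1:]))

    def test_summarize_single_probe_passthrough_and_blocks(self):
        rng = np.random.default_rng(2)
        cols = ["A_r1", "A_r2", "B_r1", "B_r2"]
        vals = rng.normal(7, 1, (3, 4))
        probes = ExpressionMatrix(
            pd.DataFrame(vals, index=["m1_p1", "m1_p2", "m2_p1"], columns=cols)
        )
        pm = {"m1_p1": "m1", "m1_p2": "m1", "m2_p1": "m2"}
        out = median_polish_summarize(probes, pm)
        assert sorted(out.feature_ids) == ["m1", "m2"]
        np.testing.assert_allclose(out.values.loc["m2"], vals[2])

    def test_summarize_invariant_to_probe_row_order(self):
        rng = np.random.default_rng(5)
        cols = ["A_r1", "A_r2", "B_r1", "B_r2", "B_r3"]
        ids = [f"m1_p{i}" for i in range(4)]
        df = pd.DataFrame(rng.normal(size=(4, 5)), index=ids, columns=cols)
        pm = {i: "m1" for i in ids}
        a = median_polish_summarize(ExpressionMatrix(df), pm)
        b = median_polish_summarize(ExpressionMatrix(df.iloc[::-1]), pm)
        np.testing.assert_allclose(
            a.values.loc["m1"].to_numpy(), b.values.loc["m1"].to_numpy(), atol=1e-12
        )


# ------------------------------------------------------ expressed calls


class TestCallExpressed:
    @pytest.fixture()
    def matrix(self):
        rng = np.random.default_rng(0)
        cols = ["A_r1", "A_r2", "B_r1", "B_r2"]
        vals = np.vstack(
            [
                rng.normal(8.0, 0.1, (4, 4)),  # expressed everywhere
                rng.normal(4.0, 0.1, (4, 4)),  # background
            ]
        )
        return make_matrix(vals, cols, index=[f"hi{i}" for i in range(4)] + [f"lo{i}" for i in range(4)])

    def test_threshold_below_minimum_takes_all(self, matrix):
        assert call_expressed(matrix, min_mean=0.0) == set(matrix.feature_ids)

    def test_threshold_above_maximum_takes_none(self, matrix):
        assert call_expressed(matrix, min_mean=20.0) == set()

    def test_planted_expressed_set_recovered(self, matrix):
        assert call_expressed(matrix, min_mean=6.0) == {f"hi{i}" for i in range(4)}

    def test_min_celltypes_bound_validated(self, matrix):
        with pytest.raises(ValueError):
            call_expressed(matrix, min_mean=6.0, min_celltypes=5)


# ------------------------------------------------------ qPCR helper


@pytest.mark.parametrize(
    "cts, expected",
    [
        ((20.0, 20.0, 20.0, 20.0), 1.0),  # no change
        ((22.0, 20.0, 21.0, 20.0), 0.5),  # ddCt = +1
        ((19.0, 20.0, 21.0, 20.0), 4.0),  # ddCt = -2
    ],
)
def test_delta_delta_ct(cts, expected):
    assert delta_delta_ct(*cts) == pytest.approx(expected)


def test_delta_delta_ct_rejects_nonfinite():
    with pytest.raises(ValueError):
        delta_delta_ct(np.nan, 20.0, 20.0, 20.0)
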
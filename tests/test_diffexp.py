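"""Moderated t, BH adjustment, correlation clustering, Venn partition."""

import itertools
import os
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from seedscape.diffexp import (
    ModeratedT,
    ModeratedTResults,
    benjamini_hochberg,
    fit_variance_prior,
    pearson_cluster,
    venn_partition,
)
from seedscape.expression import ExpressionMatrix

from conftest import make_matrix, two_group_columns


def _null_matrix(seed, n=200, per_group=3, d0=4.0, s0_sq=0.05):
    rng = np.random.default_rng(seed)
    var = d0 * s0_sq / rng.chisquare(d0, n)
    x = rng.normal(0, 1, (n, 2 * per_group)) * np.sqrt(var)[:, None]
    return make_matrix(x, two_group_columns(per_group))


class TestModeratedT:
    def test_equal_variances_reduce_to_ordinary_t(self):
        rng = np.random.default_rng(0)
        # every feature = its own offset plus one shared pattern, so all
        # residual variances are identical and shrinkage changes nothing
        pattern = rng.normal(0, 1, 6)
        shifts = rng.normal(0, 2, (30, 1))
        x = shifts + pattern[None, :]
        m = make_matrix(x, two_group_columns())
        res = ModeratedT(m, "A", "B").fit()
        t_ref = stats.ttest_ind(x[:, :3], x[:, 3:], axis=1).statistic
        assert np.isinf(res.d0)
        np.testing.assert_allclose(res.table["t"], t_ref, atol=1e-10)

    def test_zero_mean_difference_gives_null_result(self):
        rng = np.random.default_rng(1)
        half = rng.normal(0, 1, (10, 3))
        x = np.hstack([half, half[:, ::-1]])  # identical group means and spreads
        res = ModeratedT(make_matrix(x, two_group_columns()), "A", "B").fit()
        np.testing.assert_allclose(res.table["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.table["pvalue"], 1.0, atol=1e-12)

    def test_posterior_variance_between_prior_and_sample(self):
        res = ModeratedT(_null_matrix(2), "A", "B").fit()
        lo = np.minimum(res.table["s2"], res.s0_squared)
        hi = np.maximum(res.table["s2"], res.s0_squared)
        inside = (res.table["s2_post"] >= lo - 1e-12) & (res.table["s2_post"] <= hi + 1e-12)
        assert inside.all()

    def test_prior_recovery_from_scaled_inverse_chisquare(self):
        rng = np.random.default_rng(20)
        d0_true, s0_true, df = 4.0, 0.05, 4.0
        var = d0_true * s0_true / rng.chisquare(d0_true, 2000)
        s2 = var * rng.chisquare(df, 2000) / df
        d0, s0_sq = fit_variance_prior(s2, np.full(2000, df))
        assert abs(d0 - d0_true) < 1.0
        assert abs(s0_sq - s0_true) / s0_true < 0.20

    def test_null_pvalues_uniform(self):
        for seed in (0, 1, 2):
            res = ModeratedT(_null_matrix(seed, n=5000), "A", "B").fit()
            assert stats.kstest(res.table["pvalue"], "uniform").pvalue > 0.01

    def test_requires_replicates(self):
        m = make_matrix(np.zeros((3, 3)), ["A_r1", "A_r2", "B_r1"])
        with pytest.raises(ValueError, match=">= 2"):
            ModeratedT(m, "A", "B")

    def test_agrees_with_limma(self):
        """Independent oracle: R limma's eBayes on the same two-group design."""
        rng = np.random.default_rng(42)
        var = 4 * 0.05 / rng.chisquare(4, 40)
        x = rng.normal(0, 1, (40, 6)) * np.sqrt(var)[:, None]
        x[:5, :3] += 1.0
        df = pd.DataFrame(
            x, index=[f"g{i:02d}" for i in range(40)], columns=two_group_columns()
        )
        res = ModeratedT(ExpressionMatrix(df), "A", "B").fit()
        with tempfile.TemporaryDirectory() as td:
            mat, out = os.path.join(td, "m.tsv"), os.path.join(td, "out.tsv")
            df.to_csv(mat, sep="\t")
            script = f"""
suppressMessages(library(limma))
x <- as.matrix(read.delim("{mat}", row.names=1))
fit <- eBayes(lmFit(x, cbind(Intercept=1, AvsB=c(1,1,1,0,0,0))))
out <- data.frame(t=fit$t[,"AvsB"], p=fit$p.value[,"AvsB"],
                  d0=fit$df.prior, s02=fit$s2.prior)
write.table(out, "{out}", sep="\\t", quote=FALSE)
"""
            proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
            assert proc.returncode == 0, proc.stderr
            lim = pd.read_csv(out, sep="\t")
        assert res.d0 == pytest.approx(lim["d0"].iloc[0], abs=1e-6)
        assert res.s0_squared == pytest.approx(lim["s02"].iloc[0], rel=1e-6)
        np.testing.assert_allclose(res.table["t"], lim["t"], atol=1e-9)
        np.testing.assert_allclose(res.table["pvalue"], lim["p"], atol=1e-9)

    def test_summary_mentions_contrast(self):
        res = ModeratedT(_null_matrix(4, n=20), "A", "B").fit()
        text = res.summary()
        assert "A vs B" in text and "prior df" in text


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.037]), [0.037])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2] * 5), [0.2] * 5)

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_never_decreases_and_order_invariant(self, ps):
        adj = benjamini_hochberg(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        perm = np.argsort(ps, kind="stable")[::-1]
        adj_perm = benjamini_hochberg(np.asarray(ps)[perm])
        np.testing.assert_allclose(adj[perm], adj_perm, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


def _average_linkage_oracle(dist):
    """Brute-force O(n^3) UPGMA merge heights."""
    clusters = {i: [i] for i in range(len(dist))}
    heights = []
    next_id = len(dist)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[i][j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return sorted(heights)


class TestPearsonCluster:
    def test_identical_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 10)
        x = np.stack([base, base, rng.normal(0, 1, 10)], axis=1)
        linkage, _, order = pearson_cluster(make_matrix(x, ["s1", "s2", "s3"]))
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(order[:2]) == {"s1", "s2"}

    def test_planted_pair_merges_first(self):
        rng = np.random.default_rng(1)
        shared = rng.normal(0, 1, 12)
        x = np.stack(
            [shared + rng.normal(0, 0.05, 12), shared + rng.normal(0, 0.05, 12), rng.normal(0, 1, 12)],
            axis=1,
        )
        _, _, order = pearson_cluster(make_matrix(x, ["p1", "p2", "q"]))
        assert set(order[:2]) == {"p1", "p2"}

    def test_merge_heights_match_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (10, 6))
        linkage, _, _ = pearson_cluster(make_matrix(x, [f"s{i}" for i in range(6)]))
        dist = 1 - np.corrcoef(x.T)
        np.testing.assert_allclose(
            sorted(linkage[:, 2]), _average_linkage_oracle(dist), atol=1e-8
        )

    def test_zero_variance_feature_dropped(self):
        rng = np.random.default_rng(3)
        x = np.vstack([np.full(4, 5.0), rng.normal(0, 1, (5, 4))])
        linkage, ordered, _ = pearson_cluster(
            make_matrix(x, [f"s{i}" for i in range(4)])
        )
        assert "f0" not in ordered.index


def _results_from_table(pvals, logfcs, ids, a="X", b="Y"):
    table = pd.DataFrame(
        {"logFC": logfcs, "pvalue": pvals, "adj_pvalue": benjamini_hochberg(pvals)},
        index=ids,
    )
    return ModeratedTResults(table, d0=4.0, s0_squared=0.05, group_a=a, group_b=b, n_a=2, n_b=2)


class TestVennPartition:
    def test_no_feature_significant_all_none(self):
        ids = ["m1", "m2"]
        res = {k: _results_from_table([0.5, 0.9], [1, -1], ids) for k in ("ab", "ac", "bc")}
        assignment, counts = venn_partition(res)
        assert counts == {"none": 2}

    def test_center_region(self):
        ids = ["m1"]
        res = {k: _results_from_table([0.001], [1], ids) for k in ("ab", "ac", "bc")}
        assignment, _ = venn_partition(res)
        assert assignment["m1"] == "ab&ac&bc"

    def test_planted_lineage_pattern_recovered(self):
        # three cell types, features with effects confined to one type
        rng = np.random.default_rng(0)
        cols = [f"{ct}_r{i}" for ct in ("EC", "EP", "HE") for i in (1, 2, 3)]
        x = rng.normal(0, 0.01, (3, 9))
        x[0, 0:3] += 2.0  # EC-specific: significant in EC-EP and EC-HE only
        x[1, 3:6] += 2.0  # EP-specific
        # feature 2: no effect anywhere
        m = make_matrix(x, cols)
        res = {
            "EC-EP": ModeratedT(m, "EC", "EP").fit(),
            "EC-HE": ModeratedT(m, "EC", "HE").fit(),
            "EP-HE": ModeratedT(m, "EP", "HE").fit(),
        }
        assignment, counts = venn_partition(res, alpha=0.05)
        assert assignment["f0"] == "EC-EP&EC-HE"
        assert assignment["f1"] == "EC-EP&EP-HE"
        assert assignment["f2"] == "none"

    def test_mismatched_universes_rejected(self):
        res = {
            "ab": _results_from_table([0.5], [1], ["m1"]),
            "ac": _results_from_table([0.5], [1], ["m2"]),
            "bc": _results_from_table([0.5], [1], ["m1"]),
        }
        with pytest.raises(ValueError, match="universe"):
            venn_partition(res)
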
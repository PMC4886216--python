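"""Moderated t, probe collapsing, BH adjustment and gene selection."""
from __future__ import annotations

import os
import shutil
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import heartnet as hn
from heartnet.diffexpr import bh_adjust


def _two_group_expr(X, nA, nB):
    cols = [f"a{i}" for i in range(nA)] + [f"b{i}" for i in range(nB)]
    values = pd.DataFrame(X, index=[f"g{i}" for i in range(X.shape[0])], columns=cols)
    meta = pd.DataFrame(
        {"group": ["A"] * nA + ["B"] * nB,
         "replicate": list(range(1, nA + 1)) + list(range(1, nB + 1))},
        index=cols,
    )
    return hn.ExpressionMatrix(values, meta)


AB = hn.Contrast("AvsB", ("A",), ("B",))


class TestCollapseProbes:
    @pytest.fixture()
    def probe_expr(self):
        rng = np.random.default_rng(0)
        X = rng.normal(8, 1, (10, 6))
        X[3] = 8 + 3 * rng.normal(size=6)  # high-variance probe of geneB
        cols = [f"s{i}" for i in range(6)]
        values = pd.DataFrame(X, index=[f"p{i}" for i in range(10)], columns=cols)
        meta = pd.DataFrame(
            {"group": ["A"] * 3 + ["B"] * 3, "replicate": [1, 2, 3] * 2}, index=cols
        )
        pmap = pd.DataFrame(
            {
                "probe": [f"p{i}" for i in range(10)],
                "gene": ["geneA", "geneA", "geneA", "geneB", "geneB",
                         "geneC", "geneC", "geneC", "geneC", "geneD"],
            }
        )
        return hn.ExpressionMatrix(values, meta), pmap

    def test_many_probes_collapse_to_one_row_per_gene(self, probe_expr):
        expr, pmap = probe_expr
        out = hn.collapse_probes(expr, pmap)
        assert list(out.genes) == ["geneA", "geneB", "geneC", "geneD"]

    def test_max_variance_rule_keeps_most_variable_probe(self, probe_expr):
        expr, pmap = probe_expr
        out = hn.collapse_probes(expr, pmap, rule="max-variance")
        assert np.array_equal(out.values.loc["geneB"], expr.values.loc["p3"])

    def test_single_probe_gene_passes_through(self, probe_expr):
        expr, pmap = probe_expr
        out = hn.collapse_probes(expr, pmap)
        assert np.array_equal(out.values.loc["geneD"], expr.values.loc["p9"])

    def test_mean_rule_averages(self, probe_expr):
        expr, pmap = probe_expr
        out = hn.collapse_probes(expr, pmap, rule="mean")
        expected = expr.values.loc[["p0", "p1", "p2"]].mean()
        assert np.allclose(out.values.loc["geneA"], expected)

    def test_unmapped_probes_dropped_with_warning(self, probe_expr):
        expr, pmap = probe_expr
        with pytest.warns(UserWarning, match="dropping"):
            out = hn.collapse_probes(expr, pmap.iloc[:9])
        assert "geneD" not in out.genes

    def test_disjoint_map_is_an_error(self, probe_expr):
        expr, _ = probe_expr
        bad = pd.DataFrame({"probe": ["x1"], "gene": ["y"]})
        with pytest.raises(ValueError, match="no probe"):
            hn.collapse_probes(expr, bad)


class TestModeratedT:
    def test_shrinkage_off_limit_equals_ordinary_t(self):
        rng = np.random.default_rng(1)
        expr = _two_group_expr(rng.normal(0, 1, (50, 8)), 4, 4)
        res = hn.moderated_t_test(expr, AB, d0=0.0, s02=1.0)
        A = expr.values.iloc[:, :4].to_numpy()
        B = expr.values.iloc[:, 4:].to_numpy()
        ref = stats.ttest_ind(A, B, axis=1, equal_var=True)
        assert np.allclose(res.table["t"], ref.statistic, atol=1e-10)
        assert np.allclose(res.table["pval"], ref.pvalue, atol=1e-10)

    def test_full_shrinkage_limit_pins_variance_to_prior(self):
        rng = np.random.default_rng(2)
        expr = _two_group_expr(rng.normal(0, 1, (30, 6)), 3, 3)
        res = hn.moderated_t_test(expr, AB, d0=np.inf, s02=0.7)
        assert np.allclose(res.table["s2_post"], 0.7)

    def test_posterior_variance_lies_between_prior_and_sample(self):
        rng = np.random.default_rng(3)
        expr = _two_group_expr(rng.normal(0, 1, (200, 6)) * rng.uniform(0.3, 2, (200, 1)), 3, 3)
        res = hn.moderated_t_test(expr, AB)
        lo = np.minimum(res.table["s2"], res.s02)
        hi = np.maximum(res.table["s2"], res.s02)
        assert ((res.table["s2_post"] >= lo - 1e-12) & (res.table["s2_post"] <= hi + 1e-12)).all()
        assert res.d0 >= 0

    def test_null_type_one_error_calibrated(self):
        cfg = hn.SimulationConfig(de_fraction=0.0, seed=7)
        expr, _ = hn.simulate_timecourse(cfg)
        res = hn.moderated_t_test(expr, hn.INJURED_VS_HEALTHIER)
        frac = float((res.table["pval"] < 0.05).mean())
        assert 0.035 <= frac <= 0.065

    def test_moderation_stabilises_small_n_statistics(self):
        """At n=3 vs 3 the moderated t has smaller dispersion than the
        ordinary t on null data."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (300, 6)) * rng.uniform(0.3, 2.0, (300, 1))
            expr = _two_group_expr(X, 3, 3)
            mod = hn.moderated_t_test(expr, AB)
            ordinary = stats.ttest_ind(X[:, :3], X[:, 3:], axis=1).statistic
            wins += np.var(mod.table["t"]) < np.var(ordinary)
        assert wins >= 17

    def test_agrees_with_limma_oracle(self):
        """Cross-check the empirical-Bayes machinery against the reference
        R implementation on a heteroscedastic fixture."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(7)
        n = 120
        sds = rng.uniform(0.2, 1.5, n)
        X = rng.normal(8, 1, (n, 1)) + rng.normal(0, 1, (n, 12)) * sds[:, None]
        X[:10, :6] += 1.5
        expr = _two_group_expr(X, 6, 6)
        res = hn.moderated_t_test(expr, AB)
        with tempfile.TemporaryDirectory() as td:
            expr.values.to_csv(os.path.join(td, "x.csv"))
            rcode = f"""
            x <- as.matrix(read.csv("{td}/x.csv", row.names=1))
            suppressMessages(library(limma))
            design <- cbind(Intercept=1, AvsB=c(rep(1,6),rep(0,6)))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,"AvsB"], p=fit$p.value[,"AvsB"],
                              d0=fit$df.prior, s02=fit$s2.prior)
            write.csv(out, "{td}/out.csv")
            """
            proc = subprocess.run(
                ["Rscript", "-e", rcode], capture_output=True, text=True
            )
            if proc.returncode != 0:
                pytest.skip(f"limma unavailable: {proc.stderr[-200:]}")
            lim = pd.read_csv(os.path.join(td, "out.csv"), index_col=0)
        assert res.d0 == pytest.approx(lim["d0"].iloc[0], rel=1e-8)
        assert res.s02 == pytest.approx(lim["s02"].iloc[0], rel=1e-8)
        assert np.allclose(res.table["t"], lim["t"], atol=1e-10)
        assert np.allclose(res.table["pval"], lim["p"], atol=1e-10)

    def test_too_few_samples_rejected(self, tiny_expr):
        with pytest.raises(ValueError, match="2 samples"):
            hn.moderated_t_test(tiny_expr, hn.Contrast("bad", ("A",), ("missing",)))

    def test_contrast_sides_must_be_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            hn.Contrast("bad", ("A", "B"), ("B",))


class TestBHAdjust:
    def test_hand_worked_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_value_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_matches_brute_force_step_up(self):
        def brute(p):
            p = np.asarray(p, float)
            n = len(p)
            order = np.argsort(p, kind="mergesort")
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                adj[i] = running
            return adj

        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 51)))
            assert np.allclose(bh_adjust(p), brute(p), atol=1e-12)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(1)
        p = rng.random(500)
        ref = statsmodels.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref, atol=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_monotone_in_rank_and_bounded(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj <= 1.0 + 1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


class TestSelectGenes:
    def test_strict_inequality_at_threshold(self):
        table = pd.DataFrame(
            {"lfc": 0.0, "s2": 1.0, "df": 4.0, "s2_post": 1.0, "t": 0.0,
             "pval": [0.001, 0.002, 0.003], "fdr": [0.004, 0.005, 0.006]},
            index=["g1", "g2", "g3"],
        )
        res = hn.DEResult(table=table, d0=1.0, s02=1.0, contrast=AB)
        sel = hn.select_genes(res, 0.005)
        assert sel.genes == ("g1",)
        assert sel.name == "AvsB"

    def test_permissive_threshold_returns_all(self):
        table = pd.DataFrame(
            {"lfc": 0.0, "s2": 1.0, "df": 4.0, "s2_post": 1.0, "t": 0.0,
             "pval": [0.1, 0.2], "fdr": [0.5, 0.9]},
            index=["g1", "g2"],
        )
        res = hn.DEResult(table=table, d0=1.0, s02=1.0, contrast=AB)
        assert len(hn.select_genes(res, 1 - 1e-9)) == 2

    def test_threshold_must_be_a_proportion(self):
        table = pd.DataFrame(
            {"lfc": [0.0], "s2": [1.0], "df": [4.0], "s2_post": [1.0],
             "t": [0.0], "pval": [0.1], "fdr": [0.1]}, index=["g"],
        )
        res = hn.DEResult(table=table, d0=1.0, s02=1.0, contrast=AB)
        with pytest.raises(ValueError):
            hn.select_genes(res, 1.5)

    def test_planted_genes_recovered_at_large_effect(self):
        """Strongly responsive genes are selected at FDR < 0.005 with high
        recall on a dedicated large-effect simulation."""
        cfg = hn.SimulationConfig(
            n_genes=2000, n_modules=0, module_sizes=(), de_fraction=0.05,
            effect_size=6.0, n_planted_hubs=0, seed=21,
        )
        expr, truth = hn.simulate_timecourse(cfg)
        assert len(truth.de_genes) == 100
        res = hn.moderated_t_test(expr, hn.INJURED_VS_HEALTHIER)
        sel = set(hn.select_genes(res, 0.005).genes)
        recall = len(sel & set(truth.de_genes)) / len(truth.de_genes)
        assert recall >= 0.9
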
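"""Differential expression: moderated t, BH FDR, and contrast set algebra."""

import dataclasses
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirimprint import (
    SimulationConfig,
    bh_fdr,
    fit_contrast,
    make_genome,
    place_features,
    select_de,
    simulate_expression,
)
from conftest import toy_expression


def brute_force_bh(p):
    """Independent step-up oracle: sort, p*m/rank, cumulative min from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestModeratedT:
    def test_identical_values_give_null_result(self):
        values = np.tile([5.0, 7.0, 9.0], (6, 1)).T  # 3 miRNAs, same in all samples
        expr = toy_expression(values, ["A"] * 3 + ["B"] * 3)
        res = fit_contrast(expr, "A", "B")
        assert np.allclose(res.table["log2_fc"], 0.0)
        assert np.allclose(res.table["p_value"], 1.0)

    def test_infinite_prior_df_gives_pooled_prior_z(self):
        rng = np.random.default_rng(3)
        values = rng.normal(8, 1, size=(30, 6))
        expr = toy_expression(values, ["A"] * 3 + ["B"] * 3)
        res = fit_contrast(expr, "A", "B", prior_df=np.inf, prior_var=0.5)
        a = values[:, :3].mean(axis=1)
        b = values[:, 3:].mean(axis=1)
        expect = (a - b) / np.sqrt(0.5 * (1 / 3 + 1 / 3))
        assert np.allclose(res.table["t"], expect)

    def test_zero_prior_df_is_ordinary_pooled_t(self):
        """With no shrinkage the statistic equals the textbook pooled
        two-sample t on a 6-sample toy matrix."""
        rng = np.random.default_rng(9)
        values = rng.normal(0, 1, size=(10, 6)) + np.linspace(0, 2, 10)[:, None]
        expr = toy_expression(values, ["A"] * 3 + ["B"] * 3)
        res = fit_contrast(expr, "A", "B", prior_df=0)
        a, b = values[:, :3], values[:, 3:]
        sp2 = (a.var(axis=1, ddof=1) * 2 + b.var(axis=1, ddof=1) * 2) / 4
        expect_t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert np.allclose(res.table["t"], expect_t)
        from scipy import stats

        assert np.allclose(res.table["p_value"], 2 * stats.t.sf(np.abs(expect_t), 4))

    def test_zero_variance_row_handled_via_shrinkage(self):
        rng = np.random.default_rng(5)
        values = rng.normal(8, 1, size=(20, 6))
        values[0] = [9, 9, 9, 7, 7, 7]  # flat within groups, 2.0 apart
        expr = toy_expression(values, ["A"] * 3 + ["B"] * 3)
        res = fit_contrast(expr, "A", "B")
        assert np.isfinite(res.table["t"].iloc[0])
        assert res.table["p_value"].iloc[0] < 0.05

    def test_missing_group_raises(self):
        values = np.zeros((3, 6))
        expr = toy_expression(values, ["A"] * 3 + ["B"] * 3)
        with pytest.raises(ValueError):
            fit_contrast(expr, "A", "C")

    def test_matches_limma_oracle(self, tmp_path):
        """Bioconductor limma (lmFit + eBayes) on the same matrix is the
        independent oracle for prior fit, t, and p."""
        rng = np.random.default_rng(7)
        n, na, nb = 40, 3, 3
        sd = np.exp(rng.normal(-1, 0.6, n))
        base = rng.normal(8, 1, n)
        eff = np.where(rng.random(n) < 0.3, rng.normal(0, 1.5, n), 0.0)
        a = base[:, None] + eff[:, None] + rng.normal(0, sd[:, None], (n, na))
        b = base[:, None] + rng.normal(0, sd[:, None], (n, nb))
        values = np.hstack([a, b])
        expr = toy_expression(values, ["A"] * na + ["B"] * nb)
        mat_path = tmp_path / "x.tsv"
        expr.values.to_csv(mat_path, sep="\t")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{mat_path}", row.names=1))
            group <- factor(c(rep("A",{na}), rep("B",{nb})), levels=c("A","B"))
            design <- model.matrix(~0+group)
            fit <- lmFit(x, design)
            ct <- makeContrasts(groupA-groupB, levels=design)
            fit2 <- eBayes(contrasts.fit(fit, ct))
            out <- data.frame(lfc=fit2$coefficients[,1], t=fit2$t[,1],
                              p=fit2$p.value[,1], d0=fit2$df.prior, s0=fit2$s2.prior)
            write.table(out, "{tmp_path / 'limma.tsv'}", sep="\t", quote=FALSE)
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "oracle.R")], check=True, capture_output=True
        )
        lim = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)
        res = fit_contrast(expr, "A", "B")
        assert res.prior_df == pytest.approx(lim["d0"].iloc[0], rel=1e-6)
        assert res.prior_var == pytest.approx(lim["s0"].iloc[0], rel=1e-6)
        np.testing.assert_allclose(res.table["t"], lim["t"], rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(res.table["p_value"], lim["p"], rtol=1e-8, atol=1e-12)
        np.testing.assert_allclose(res.table["log2_fc"], lim["lfc"], rtol=1e-8)


class TestBHFDR:
    def test_worked_examples(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=60
        )
    )
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), rtol=1e-12, atol=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=2, max_size=40
        )
    )
    def test_rank_monotone_and_bounded(self, p):
        adj = bh_fdr(p)
        assert np.all((adj >= 0) & (adj <= 1))
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestSelectDE:
    def _three_contrasts(self, values, seed=0):
        groups = ["NHDF"] * 3 + ["iPSC"] * 3 + ["ESC"] * 3
        expr = toy_expression(values, groups)
        return [
            fit_contrast(expr, "iPSC", "NHDF"),
            fit_contrast(expr, "ESC", "NHDF"),
            fit_contrast(expr, "ESC", "iPSC"),
        ]

    def test_empty_results_give_empty_sets(self):
        rng = np.random.default_rng(0)
        contrasts = self._three_contrasts(rng.normal(8, 0.3, size=(30, 9)))
        sel = select_de(contrasts, fdr_cutoff=1e-12)
        assert sel.both == frozenset() and sel.both_min_fold == frozenset()

    def test_strong_both_member_in_fold_set(self):
        rng = np.random.default_rng(1)
        values = rng.normal(8, 0.1, size=(40, 9))
        values[0, 3:] += 1.4  # ~2.6-fold up in both pluripotent groups
        sel = select_de(self._three_contrasts(values))
        assert "m000" in sel.both and "m000" in sel.both_min_fold

    def test_set_algebra_identity(self):
        rng = np.random.default_rng(2)
        values = rng.normal(8, 0.3, size=(60, 9))
        values[:10, 3:9] += 1.0  # both
        values[10:15, 3:6] += 1.5  # iPSC only
        sel = select_de(self._three_contrasts(values))
        assert len(sel.both) + len(sel.discordant) == len(sel.union_vs_reference)
        assert sel.both_min_fold <= sel.both
        assert sel.both & sel.discordant == frozenset()

    def test_missing_contrast_rejected(self):
        rng = np.random.default_rng(3)
        contrasts = self._three_contrasts(rng.normal(8, 0.3, size=(10, 9)))
        with pytest.raises(ValueError):
            select_de(contrasts[:2])

    def test_planted_recovery_on_synthetic_design(self):
        """100 planted DE of 800 at effect 1.5, sd 0.25: the 'both' set
        recovers >=90% of planted with <=10% false discoveries (20 seeds)."""
        recalls, fdps = [], []
        for seed in range(20):
            cfg = SimulationConfig(
                de_fraction=100 / 800, effect_log2fc=1.5, noise_sd=0.25,
                n_planted_clusters=0, imprinted_near_cluster_fraction=0.0, seed=seed,
            )
            genome = make_genome(cfg)
            mirnas, _, truth = place_features(genome, cfg)
            expr = simulate_expression(mirnas, truth, cfg)
            sel = select_de(
                [
                    fit_contrast(expr, "iPSC", "NHDF"),
                    fit_contrast(expr, "ESC", "NHDF"),
                    fit_contrast(expr, "ESC", "iPSC"),
                ]
            )
            planted = truth.all_de_ids()
            recalls.append(len(sel.both & planted) / len(planted))
            fdps.append(len(sel.both - planted) / max(1, len(sel.both)))
        assert np.mean(recalls) >= 0.90
        assert np.mean(fdps) <= 0.10

    def test_null_fdr_control(self):
        """With no planted effects the average fraction called at FDR<=0.05
        stays at or below the nominal level (tolerance 0.02)."""
        fracs = []
        for seed in range(10):
            cfg = SimulationConfig(
                de_fraction=0.0, n_planted_clusters=0,
                imprinted_near_cluster_fraction=0.0, n_mirnas_total=400, seed=seed,
            )
            genome = make_genome(cfg)
            mirnas, _, truth = place_features(genome, cfg)
            expr = simulate_expression(mirnas, truth, cfg)
            res = fit_contrast(expr, "iPSC", "NHDF")
            fracs.append(np.mean(res.table["fdr"] <= 0.05))
        assert np.mean(fracs) <= 0.07
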
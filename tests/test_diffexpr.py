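import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import polygamma

from demeta.diffexpr import (
    EBHyperparams,
    bh_adjust,
    de_analysis,
    estimate_hyperparams,
    moderated_t,
    summarize_genes,
    trigamma_inverse,
)

from conftest import make_dataset


def brute_force_bh(p):
    """Step-up definition: adj_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestSummaries:
    def test_hand_computed_example(self):
        ds = make_dataset([[2, 4, 1, 1]], ["c1", "c2"], ["n1", "n2"])
        s = summarize_genes(ds).iloc[0]
        assert s["mean_diff"] == 2.0
        assert s["s2"] == 1.0  # ((1)*2 + (1)*0)/2
        assert s["df"] == 2.0
        assert s["v"] == 1.0

    def test_identical_groups_zero_diff(self):
        ds = make_dataset([[3, 5, 3, 5]], ["c1", "c2"], ["n1", "n2"])
        assert summarize_genes(ds).iloc[0]["mean_diff"] == 0.0

    def test_constant_gene_zero_variance_allowed(self):
        ds = make_dataset([[7, 7, 7, 7]], ["c1", "c2"], ["n1", "n2"])
        assert summarize_genes(ds).iloc[0]["s2"] == 0.0

    def test_single_sample_group_rejected(self):
        ds = make_dataset([[1, 2, 3]], ["c1"], ["n1", "n2"])
        with pytest.raises(ValueError, match=">=2 samples"):
            summarize_genes(ds)


class TestHyperparams:
    def test_trigamma_inverse_identity(self):
        target = float(polygamma(1, 2.0))
        assert abs(trigamma_inverse(target) - 2.0) < 1e-8

    def test_recovery_from_hierarchical_simulation(self):
        """(d0, s0^2) recovered within 20% from 5000 simulated pooled variances."""
        rng = np.random.default_rng(42)
        d0, s02, d = 4.0, 0.05, 10
        sigma2 = s02 * d0 / rng.chisquare(d0, size=5000)
        s2 = sigma2 * rng.chisquare(d, size=5000) / d
        summ = pd.DataFrame(
            {"mean_diff": 0.0, "s2": s2, "df": float(d), "v": 0.1},
            index=[f"G{i}" for i in range(5000)],
        )
        est = estimate_hyperparams(summ)
        assert abs(est.d0 - d0) / d0 < 0.2
        assert abs(est.s02 - s02) / s02 < 0.2

    def test_equal_variances_give_infinite_d0(self):
        summ = pd.DataFrame(
            {"mean_diff": 0.0, "s2": 0.5, "df": 10.0, "v": 0.1},
            index=[f"G{i}" for i in range(20)],
        )
        est = estimate_hyperparams(summ)
        assert math.isinf(est.d0)

    def test_too_few_genes_rejected(self):
        summ = pd.DataFrame(
            {"mean_diff": 0.0, "s2": [0.5] * 5 + [0.0] * 10,
             "df": 10.0, "v": 0.1},
            index=[f"G{i}" for i in range(15)],
        )
        with pytest.raises(ValueError, match=">=10 genes"):
            estimate_hyperparams(summ)


class TestModeratedT:
    def test_hand_computed_example(self):
        summ = pd.DataFrame(
            {"mean_diff": [1.0], "s2": [0.5], "df": [4.0], "v": [0.2]}, index=["g"]
        )
        res = moderated_t(summ, EBHyperparams(d0=4.0, s02=1.0))
        # s~^2 = (4*1 + 4*0.5)/8 = 0.75; t = 1/sqrt(0.15); df = 8
        assert res.loc["g", "t"] == pytest.approx(1.0 / math.sqrt(0.15), rel=1e-12)
        assert res.loc["g", "df"] == 8.0

    def test_zero_prior_df_equals_pooled_t(self):
        """With d0 -> 0 the statistic is the ordinary two-sample pooled t."""
        rng = np.random.default_rng(5)
        values = rng.standard_normal((40, 10))
        ds = make_dataset(values, [f"c{i}" for i in range(5)], [f"n{i}" for i in range(5)])
        res = moderated_t(summarize_genes(ds), None)
        t_ref, p_ref = stats.ttest_ind(values[:, :5], values[:, 5:], axis=1)
        assert np.max(np.abs(res["t"].to_numpy() - t_ref)) < 1e-10
        assert np.max(np.abs(res["p"].to_numpy() - p_ref)) < 1e-10

    def test_null_point(self):
        summ = pd.DataFrame(
            {"mean_diff": [0.0], "s2": [0.5], "df": [4.0], "v": [0.2]}, index=["g"]
        )
        res = moderated_t(summ, EBHyperparams(d0=4.0, s02=1.0))
        assert res.loc["g", "t"] == 0.0
        assert res.loc["g", "p"] == 1.0

    def test_zero_variance_gene_rescued_by_moderation(self):
        summ = pd.DataFrame(
            {"mean_diff": [1.0], "s2": [0.0], "df": [4.0], "v": [0.5]}, index=["g"]
        )
        res = moderated_t(summ, EBHyperparams(d0=2.0, s02=0.04))
        assert np.isfinite(res.loc["g", "t"])
        assert res.loc["g", "p"] > 0

    def test_abs_t_monotone_decreasing_in_prior_variance(self):
        summ = pd.DataFrame(
            {"mean_diff": [1.0], "s2": [0.5], "df": [4.0], "v": [0.2]}, index=["g"]
        )
        ts = [
            abs(moderated_t(summ, EBHyperparams(d0=4.0, s02=s02)).loc["g", "t"])
            for s02 in (0.1, 0.5, 1.0, 2.0)
        ]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_infinite_d0_uses_normal_reference(self):
        summ = pd.DataFrame(
            {"mean_diff": [1.0], "s2": [0.5], "df": [4.0], "v": [0.25]}, index=["g"]
        )
        res = moderated_t(summ, EBHyperparams(d0=math.inf, s02=1.0))
        t = 1.0 / math.sqrt(1.0 * 0.25)
        assert res.loc["g", "t"] == pytest.approx(t)
        assert res.loc["g", "p"] == pytest.approx(2 * stats.norm.sf(t), rel=1e-12)


class TestBHAdjust:
    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_value_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_capped_at_one(self):
        assert np.allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_and_dominating(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(1e-6, 1.0, size=100)
        adj = bh_adjust(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


def test_de_analysis_ranks_are_permutation():
    rng = np.random.default_rng(9)
    ds = make_dataset(
        rng.standard_normal((30, 12)),
        [f"c{i}" for i in range(6)],
        [f"n{i}" for i in range(6)],
    )
    res = de_analysis(ds)
    assert sorted(res["rank"]) == list(range(1, 31))
    assert np.all(res["p_adj"] >= res["p"] - 1e-15)


def test_global_null_rejection_fraction_controlled():
    """Without planted effects the BH-rejected fraction stays near zero."""
    from demeta.benchmarks import global_null_rejection_fraction

    frac = global_null_rejection_fraction(n_replicates=5, seed=3, n_genes=800)
    assert frac <= 0.05


def test_matches_limma_reference(tmp_path):
    """Independent oracle: the eBayes fit from the reference implementation."""
    rng = np.random.default_rng(12)
    n_genes, n1, n2 = 120, 6, 6
    sigma2 = 0.05 * 4.0 / rng.chisquare(4.0, size=n_genes)
    x = 7.0 + np.sqrt(sigma2)[:, None] * rng.standard_normal((n_genes, n1 + n2))
    x[:10, :n1] += 1.0
    mat = tmp_path / "mat.tsv"
    pd.DataFrame(
        x, index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"c{i}" for i in range(n1)] + [f"n{i}" for i in range(n2)],
    ).rename_axis("gene").to_csv(mat, sep="\t")
    script = tmp_path / "fit.R"
    script.write_text(
        """
        suppressMessages(library(limma))
        args <- commandArgs(trailingOnly=TRUE)
        x <- as.matrix(read.delim(args[1], row.names=1))
        design <- cbind(Intercept=1, Case=c(rep(1, %d), rep(0, %d)))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(gene=rownames(x), t=fit$t[, "Case"],
                          p=fit$p.value[, "Case"])
        write.table(out, args[2], sep="\\t", row.names=FALSE, quote=FALSE)
        cat(fit$df.prior, fit$s2.prior, "\\n")
        """ % (n1, n2)
    )
    out = tmp_path / "limma.tsv"
    proc = subprocess.run(
        ["Rscript", str(script), str(mat), str(out)],
        capture_output=True, text=True, check=True,
    )
    d0_ref, s02_ref = map(float, proc.stdout.split())

    ds = make_dataset(x, [f"c{i}" for i in range(n1)], [f"n{i}" for i in range(n2)])
    summ = summarize_genes(ds)
    est = estimate_hyperparams(summ)
    assert est.d0 == pytest.approx(d0_ref, rel=1e-6)
    assert est.s02 == pytest.approx(s02_ref, rel=1e-6)
    mine = moderated_t(summ, est)
    ref = pd.read_csv(out, sep="\t", index_col=0)
    assert np.allclose(mine["t"].to_numpy(), ref["t"].to_numpy(), rtol=1e-8)
    assert np.allclose(mine["p"].to_numpy(), ref["p"].to_numpy(), rtol=1e-8)
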
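"""Moderated t-test, BH correction and significance thresholds."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hemidel.dge import apply_thresholds, bh_adjust, fit_f_prior, moderated_test
from hemidel.hi_expression import DELETED, DIPLOID


def group_labels(n1, n2):
    cols = [f"D{i}" for i in range(n1)] + [f"N{i}" for i in range(n2)]
    return cols, pd.Series([DELETED] * n1 + [DIPLOID] * n2, index=cols)


def random_matrix(n_genes, n1, n2, seed=0):
    rng = np.random.default_rng(seed)
    cols, labels = group_labels(n1, n2)
    scale = rng.uniform(0.5, 2.0, size=(n_genes, 1))
    values = pd.DataFrame(
        rng.normal(5, 1, size=(n_genes, n1 + n2)) * scale,
        index=[f"g{i}" for i in range(n_genes)],
        columns=cols,
    )
    return values, labels


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_brute_force_definition(self):
        def brute(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p, kind="mergesort")
            q = np.empty(m)
            for rank_pos, idx in enumerate(order):
                j = np.arange(rank_pos, m)
                q[idx] = min(1.0, np.min(p[order][j] * m / (j + 1)))
            return q

        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 120)))
            np.testing.assert_allclose(bh_adjust(p), brute(p), rtol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 500)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_sm, rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestModeratedTest:
    def test_identical_groups_give_null_result(self):
        cols, labels = group_labels(4, 4)
        block = np.random.default_rng(1).normal(5, 1, size=(30, 4))
        values = pd.DataFrame(
            np.hstack([block, block]), columns=cols,
            index=[f"g{i}" for i in range(30)],
        )
        res = moderated_test(values, labels)
        np.testing.assert_allclose(res["log2_fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-9)

    def test_no_shrinkage_limit_equals_ordinary_t(self):
        values, labels = random_matrix(40, 6, 8, seed=2)
        res = moderated_test(values, labels, prior_df=0)
        g1 = values.iloc[:, :6].to_numpy()
        g2 = values.iloc[:, 6:].to_numpy()
        t, p = stats.ttest_ind(g1, g2, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t_mod"], t, rtol=1e-9)
        np.testing.assert_allclose(res["p"], p, rtol=1e-9)

    def test_label_swap_negates_fold_changes(self):
        values, labels = random_matrix(40, 6, 8, seed=3)
        swapped = labels.map({DELETED: DIPLOID, DIPLOID: DELETED})
        a = moderated_test(values, labels)
        b = moderated_test(values, swapped)
        np.testing.assert_allclose(a["log2_fc"], -b["log2_fc"], rtol=1e-12)
        np.testing.assert_allclose(a["p"], b["p"], rtol=1e-12)

    def test_too_small_groups_raise(self):
        values, _ = random_matrix(5, 1, 3)
        cols = values.columns
        labels = pd.Series([DELETED] + [DIPLOID] * 3, index=cols)
        with pytest.raises(ValueError):
            moderated_test(values, labels)

    def test_prior_fit_recovers_known_f_mixture(self):
        # variances drawn from s0^2 * F(d, d0): the moment fit should
        # recover d0 and s0^2 on a large sample
        rng = np.random.default_rng(9)
        d, d0, s0_sq = 10, 6.0, 2.0
        v = s0_sq * stats.f.rvs(d, d0, size=60_000, random_state=rng)
        d0_hat, s0_hat = fit_f_prior(v, d)
        assert d0_hat == pytest.approx(d0, rel=0.1)
        assert s0_hat == pytest.approx(s0_sq, rel=0.05)

    def test_matches_limma_oracle(self, tmp_path):
        """Independent cross-check against the reference empirical-Bayes
        implementation in Bioconductor (run through Rscript)."""
        values, labels = random_matrix(60, 8, 10, seed=42)
        values.iloc[:5, :8] += 2.0
        mat = tmp_path / "mat.tsv"
        out = tmp_path / "limma_out.tsv"
        values.to_csv(mat, sep="\t")
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f'x <- as.matrix(read.delim("{mat}", row.names=1))\n'
            'grp <- factor(c(rep("del",8), rep("dip",10)), levels=c("dip","del"))\n'
            "fit <- eBayes(lmFit(x, model.matrix(~grp)))\n"
            'write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2]),\n'
            f'            "{out}", sep="\\t", quote=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        oracle = pd.read_csv(out, sep="\t")
        res = moderated_test(values, labels)
        np.testing.assert_allclose(res["t_mod"], oracle["t"], rtol=1e-8)
        np.testing.assert_allclose(res["p"], oracle["p"], rtol=1e-8)


class TestThresholds:
    @pytest.mark.parametrize(
        "fc,q,status",
        [
            (1.5, 1e-6, "up"),
            (1.5, 1e-4, "ns"),  # -log10 q = 4, not > 5
            (-0.9, 1e-9, "ns"),  # |fc| below the cut
            (-1.2, 1e-7, "down"),
            (1.0, 1e-9, "ns"),  # fc must be strictly above 1
        ],
    )
    def test_status_rule(self, fc, q, status):
        df = pd.DataFrame({"gene": ["g"], "log2_fc": [fc], "p": [q], "q": [q]})
        assert apply_thresholds(df)["status"].iloc[0] == status

    def test_q_computed_from_p_when_missing(self):
        df = pd.DataFrame({"gene": list("ab"), "log2_fc": [2.0, 0.0], "p": [1e-9, 0.9]})
        out = apply_thresholds(df)
        np.testing.assert_allclose(out["q"], bh_adjust(df["p"]))
        assert out["status"].tolist() == ["up", "ns"]

    def test_natural_log_base_is_configurable(self):
        df = pd.DataFrame({"gene": ["g"], "log2_fc": [2.0], "p": [1e-3], "q": [1e-3]})
        assert apply_thresholds(df, log_base=10).status.iloc[0] == "ns"
        assert apply_thresholds(df, log_base=np.e).status.iloc[0] == "up"


def null_log2_matrix(n_genes, n1, n2, seed):
    """Gene-wise normal log2 expression with heterogeneous true variances."""
    rng = np.random.default_rng(seed)
    cols, labels = group_labels(n1, n2)
    sd = rng.lognormal(mean=-1.0, sigma=0.4, size=(n_genes, 1))
    values = pd.DataFrame(
        5.0 + sd * rng.standard_normal((n_genes, n1 + n2)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=cols,
    )
    return values, labels


def test_null_calibration_single_seed():
    """Uniform p-values under the null: rejection rate near nominal 5%."""
    values, labels = null_log2_matrix(2000, 49, 120, seed=11)
    res = moderated_test(values, labels)
    rate = float((res["p"] < 0.05).mean())
    assert 0.03 <= rate <= 0.07
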
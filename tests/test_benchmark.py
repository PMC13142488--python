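"""Differential abundance, confusion-table metrics and partial AUC."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from dialion.benchmark import (
    classify_daps,
    filter_quantifiable,
    moderated_test,
    quant_metrics,
    roc_pauc,
    species_from_protein_group,
)
from dialion.model import QuantMatrix, SampleMetadata

TRUTH = {"HUMAN": "unchanged", "YEAST": "up", "ECOLI": "down"}


def _meta(n_a=8, n_b=8):
    runs = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    return SampleMetadata(runs=tuple(runs), conditions=tuple("A" * n_a + "B" * n_b))


class TestFilterQuantifiable:
    def _matrix(self, valid_a, valid_b, n_a=8, n_b=8):
        row = [1.0] * valid_a + [np.nan] * (n_a - valid_a)
        row += [1.0] * valid_b + [np.nan] * (n_b - valid_b)
        return QuantMatrix(
            values=pd.DataFrame([row], index=["prot"], columns=list(_meta(n_a, n_b).runs))
        )

    def test_five_of_eight_kept(self):
        m = filter_quantifiable(self._matrix(5, 6), _meta(), 5)
        assert list(m.values.index) == ["prot"]

    def test_four_of_eight_dropped(self):
        m = filter_quantifiable(self._matrix(4, 8), _meta(), 5)
        assert len(m.values) == 0

    def test_single_precursor_dropped_regardless(self):
        m = filter_quantifiable(
            self._matrix(8, 8), _meta(), 5, min_precursors=2,
            precursor_counts={"prot": 1},
        )
        assert len(m.values) == 0


class TestModeratedTest:
    def test_exact_log2fc(self):
        meta = _meta(3, 3)
        vals = np.log2(np.array([[1, 1, 1, 3, 3, 3]], dtype=float))
        df = pd.DataFrame(vals, index=["p"], columns=list(meta.runs))
        # variance is zero everywhere -> epsilon-variance fallback warns
        with pytest.warns(UserWarning):
            out = moderated_test(QuantMatrix(values=df), meta)
        assert out.loc["p", "log2fc"] == pytest.approx(-np.log2(3))

    def test_null_simulation_adj_p_controlled(self):
        rng = np.random.default_rng(0)
        meta = _meta(4, 4)
        vals = rng.normal(10, 1, (200, 8))
        df = pd.DataFrame(vals, index=[f"p{i}" for i in range(200)], columns=list(meta.runs))
        out = moderated_test(QuantMatrix(values=df), meta)
        assert (out["adj_p"] < 0.05).mean() <= 0.05

    def test_infinite_prior_df_gives_pooled_variance(self):
        rng = np.random.default_rng(1)
        meta = _meta(4, 4)
        vals = rng.normal(10, 1, (50, 8))
        df = pd.DataFrame(vals, index=[f"p{i}" for i in range(50)], columns=list(meta.runs))
        strong = moderated_test(QuantMatrix(values=df), meta, prior_df=1e12)
        # with an overwhelming prior every protein shares one variance:
        # the t statistic must be proportional to log2fc
        t_like = strong["log2fc"] / np.abs(strong["log2fc"])  # sign
        order_fc = strong["log2fc"].abs().rank()
        order_p = strong["raw_p"].rank(ascending=False)
        assert (order_fc == order_p).all()

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(2)
        meta = _meta(4, 4)
        vals = rng.normal(10, 1, (100, 8))
        vals[:20, :4] += 2.0
        df = pd.DataFrame(vals, index=[f"p{i}" for i in range(100)], columns=list(meta.runs))
        out = moderated_test(QuantMatrix(values=df), meta)
        by_raw = out.sort_values("raw_p")
        assert by_raw["adj_p"].is_monotonic_increasing

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
    def test_matches_limma_oracle(self, tmp_path):
        """Cross-check the re-implemented empirical-Bayes moderated t-test
        against Bioconductor limma on one simulated dataset."""
        rng = np.random.default_rng(3)
        meta = _meta(4, 4)
        n = 120
        vals = rng.normal(12, 1, (n, 8)) * rng.uniform(0.5, 2.0, (n, 1))
        vals[:30, :4] += rng.uniform(1, 3, (30, 1))
        df = pd.DataFrame(vals, index=[f"p{i}" for i in range(n)], columns=list(meta.runs))
        ours = moderated_test(QuantMatrix(values=df), meta)

        data_path = tmp_path / "mat.tsv"
        df.to_csv(data_path, sep="\t")
        script = tmp_path / "limma_check.R"
        script.write_text(textwrap.dedent("""
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            m <- as.matrix(read.delim(args[1], row.names=1))
            design <- cbind(Intercept=1, AvsB=c(rep(1,4), rep(0,4)))
            fit <- eBayes(lmFit(m, design))
            tab <- topTable(fit, coef="AvsB", number=Inf, sort.by="none", adjust.method="BH")
            write.table(data.frame(id=rownames(tab), logFC=tab$logFC,
                        P.Value=tab$P.Value, adj.P.Val=tab$adj.P.Val),
                        args[2], sep="\\t", row.names=FALSE, quote=FALSE)
        """))
        out_path = tmp_path / "limma.tsv"
        subprocess.run(
            ["Rscript", str(script), str(data_path), str(out_path)],
            check=True, capture_output=True,
        )
        theirs = pd.read_csv(out_path, sep="\t", index_col=0)
        np.testing.assert_allclose(ours["log2fc"], theirs["logFC"], rtol=1e-6)
        np.testing.assert_allclose(ours["raw_p"], theirs["P.Value"], rtol=0.02, atol=1e-8)
        np.testing.assert_allclose(ours["adj_p"], theirs["adj.P.Val"], rtol=0.02, atol=1e-8)


class TestClassifyDaps:
    def _results(self, rows):
        idx = [r[0] for r in rows]
        return pd.DataFrame(
            {
                "log2fc": [r[1] for r in rows],
                "raw_p": [r[2] for r in rows],
                "adj_p": [r[2] for r in rows],
            },
            index=idx,
        )

    def test_expected_direction_is_tp(self):
        res = self._results([("y1_YEAST", 1.2, 0.001)])
        assert classify_daps(res, TRUTH).tp == 1

    def test_significant_unchanged_is_fp(self):
        res = self._results([("h1_HUMAN", 0.8, 0.01)])
        b = classify_daps(res, TRUTH)
        assert b.fp == 1 and b.dafdr == 1.0

    def test_wrong_direction_is_fp(self):
        res = self._results([("e1_ECOLI", 1.5, 0.001)])
        assert classify_daps(res, TRUTH).fp == 1

    def test_quiet_proteins(self):
        res = self._results([("h1_HUMAN", 0.1, 0.9), ("y1_YEAST", 0.2, 0.8)])
        b = classify_daps(res, TRUTH)
        assert (b.tn, b.fn, b.dafdr) == (1, 1, 0.0)

    def test_dafdr_formula(self):
        rows = [(f"y{i}_YEAST", 1.5, 0.001) for i in range(99)]
        rows.append(("h0_HUMAN", 0.9, 0.001))
        b = classify_daps(self._results(rows), TRUTH)
        assert (b.tp, b.fp) == (99, 1)
        assert b.dafdr == pytest.approx(0.01)

    def test_species_suffix_parsing(self):
        assert species_from_protein_group("ALBU_HUMAN") == "HUMAN"
        assert species_from_protein_group("P00330_YEAST") == "YEAST"
        assert species_from_protein_group("weird") is None


def brute_force_pauc(scores_pos, scores_neg, fpr_max=0.1):
    """Restricted Mann-Whitney oracle: integrate the ROC staircase over the
    first fpr_max * N negatives, column by column (smaller score = better).
    The column ending at the j-th false positive has height equal to the
    fraction of positives ranked before that negative; a fractional last
    column is included pro rata."""
    neg_sorted = np.sort(scores_neg)
    n_pos, n_neg = len(scores_pos), len(scores_neg)
    k_max = fpr_max * n_neg
    area = 0.0
    for j, s in enumerate(neg_sorted, start=1):
        tpr = (np.sum(scores_pos < s) + 0.5 * np.sum(scores_pos == s)) / n_pos
        if j <= math.floor(k_max):
            area += tpr / n_neg
        else:
            area += (k_max - math.floor(k_max)) / n_neg * tpr
            break
    return area


class TestRocPauc:
    def _results(self, scores_pos, scores_neg):
        rows = []
        for i, s in enumerate(scores_pos):
            rows.append((f"y{i}_YEAST", 2.0, s))
        for i, s in enumerate(scores_neg):
            rows.append((f"h{i}_HUMAN", 0.0, s))
        idx = [r[0] for r in rows]
        return pd.DataFrame(
            {"log2fc": [r[1] for r in rows], "adj_p": [r[2] for r in rows]}, index=idx
        )

    def test_perfect_ranking(self):
        res = self._results(np.linspace(0.001, 0.01, 20), np.linspace(0.5, 0.9, 20))
        assert roc_pauc(res, TRUTH) == pytest.approx(0.1)

    def test_diagonal_roc(self):
        # interleave positives and negatives perfectly: ROC follows diagonal
        n = 500
        pos = np.arange(0, 2 * n, 2) / (2 * n)
        neg = np.arange(1, 2 * n, 2) / (2 * n)
        res = self._results(pos, neg)
        assert roc_pauc(res, TRUTH) == pytest.approx(0.005, abs=0.0012)

    def test_inverted_ranking_zero(self):
        res = self._results(np.linspace(0.5, 0.9, 10), np.linspace(0.001, 0.01, 10))
        assert roc_pauc(res, TRUTH) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = rng.integers(20, 100, 2)
        pos = rng.uniform(0, 1, n_pos)
        neg = rng.uniform(0.2, 1, n_neg)
        res = self._results(pos, neg)
        ours = roc_pauc(res, TRUTH)
        oracle = brute_force_pauc(pos, neg)
        assert ours == pytest.approx(oracle, abs=2.0 / n_neg * 0.1 + 1e-6)

    @pytest.mark.parametrize("seed", [10, 11])
    def test_matches_sklearn_on_tie_free_instances(self, seed):
        from sklearn.metrics import roc_curve

        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 0.6, 80)
        neg = rng.uniform(0.3, 1.0, 120)
        res = self._results(pos, neg)
        y = np.array([1] * 80 + [0] * 120)
        fpr, tpr, _ = roc_curve(y, -np.concatenate([pos, neg]))
        mask = fpr <= 0.1
        xs = np.append(fpr[mask], 0.1)
        ys = np.append(tpr[mask], np.interp(0.1, fpr, tpr))
        expected = np.trapezoid(ys, xs)
        assert roc_pauc(res, TRUTH) == pytest.approx(expected, abs=1e-9)


class TestQuantMetrics:
    def test_constant_protein_zero_cv(self):
        meta = _meta(3, 3)
        vals = [[10.0, 10.0, 10.0, 4.0, 4.0, 4.0]]
        m = QuantMatrix(values=pd.DataFrame(vals, index=["p_HUMAN"], columns=list(meta.runs)))
        cv, fce, obs = quant_metrics(m, meta, {"HUMAN": 0.0})
        assert cv.loc["p_HUMAN", "A"] == pytest.approx(0.0)
        assert cv.loc["p_HUMAN", "B"] == pytest.approx(0.0)

    def test_exact_fold_change_zero_error(self):
        meta = _meta(2, 2)
        vals = [[8.0, 8.0, 4.0, 4.0]]
        m = QuantMatrix(values=pd.DataFrame(vals, index=["p_YEAST"], columns=list(meta.runs)))
        _, fce, obs = quant_metrics(m, meta, {"YEAST": 1.0})
        assert obs.loc["p_YEAST"] == pytest.approx(1.0)
        assert fce.loc["YEAST"] == pytest.approx(0.0)

    def test_deviation_arithmetic(self):
        meta = _meta(2, 2)
        vals = [[2**1.4, 2**1.4, 1.0, 1.0]]
        m = QuantMatrix(values=pd.DataFrame(vals, index=["p_YEAST"], columns=list(meta.runs)))
        _, fce, _ = quant_metrics(m, meta, {"YEAST": 1.0})
        assert fce.loc["YEAST"] == pytest.approx(0.4)
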
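"""CPM normalization, the NB LRT, combined BH, and DEG/DEE calling."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from exonsci.diffexpr import (DEConfig, bh_adjust, call_and_classify, cpm,
                              condition_mean_cpm, nb_lrt, run_combined_de,
                              shared_logfc_correlation)
from exonsci.quantify import CountMatrix


def matrix(X, kind="gene", features=None):
    X = np.asarray(X)
    return CountMatrix([f"c{i}" for i in range(X.shape[0])],
                       features or [f"{kind[0]}{j}" for j in range(X.shape[1])],
                       kind, sp.csr_matrix(X))


def bh_oracle(p):
    """Sort-and-scan Benjamini-Hochberg with step-up monotonization."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestCpm:
    def test_count_one_in_thousand_total(self):
        cm = matrix([[1, 999]])
        X, cells = cpm(cm)
        assert X[0, 0] == pytest.approx(1000.0)
        assert cells == ["c0"]

    def test_row_sums_are_one_million(self, rng):
        cm = matrix(rng.poisson(5, size=(30, 40)))
        X, _ = cpm(cm)
        np.testing.assert_allclose(np.asarray(X.sum(axis=1)).ravel(), 1e6)

    def test_zero_total_cell_excluded_with_warning(self):
        cm = matrix([[1, 1], [0, 0]])
        with pytest.warns(UserWarning, match="zero-total"):
            _, cells = cpm(cm)
        assert cells == ["c0"]

    def test_all_equal_cells_condition_means(self):
        cm = matrix(np.tile([[2, 8]], (6, 1)))
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=cm.cell_ids)
        means = condition_mean_cpm(cm, labels)
        np.testing.assert_allclose(means["a"], [2e5, 8e5])
        np.testing.assert_allclose(means["b"], [2e5, 8e5])


class TestNbLrt:
    def test_no_effect_p_near_one(self):
        y = np.array([5, 6, 5, 6, 5, 6, 5, 6])
        cond = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
        y = np.concatenate([y[:4], y[:4]])
        s = np.full(8, 100.0)
        p, fallback = nb_lrt(y, cond, s)
        assert p > 0.9

    def test_all_zero_feature(self):
        p, fallback = nb_lrt(np.zeros(10), np.array(["a"] * 5 + ["b"] * 5),
                             np.full(10, 50.0))
        assert p == 1.0 and not fallback

    def test_detects_strong_effect(self, rng):
        n = 100
        cond = np.array(["a"] * 50 + ["b"] * 50)
        s = np.full(n, 1000.0)
        y = rng.poisson(np.where(cond == "b", 20.0, 5.0))
        p, _ = nb_lrt(y, cond, s)
        assert p < 1e-6

    def test_type_one_error_calibrated(self, rng):
        """500 null NB features: rejection rate at 0.05 inside the 99%
        binomial band."""
        n = 150
        cond = np.array(["a"] * 75 + ["b"] * 75)
        s = rng.lognormal(6.0, 0.3, n)
        hits = 0
        n_feat = 500
        for _ in range(n_feat):
            mu = s * 3e-3
            y = rng.poisson(rng.gamma(1 / 0.3, mu * 0.3))
            p, _ = nb_lrt(y, cond, s)
            hits += p < 0.05
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_feat)
        assert abs(hits / n_feat - 0.05) < half

    def test_log2fc_recovery(self, rng):
        """Simulated log2FC = +/-1 at 200 cells/condition recovers within
        0.15, with balanced effect directions so library sizes stay stable."""
        n = 400
        cond = np.array(["young"] * 200 + ["aged"] * 200)
        s = rng.lognormal(6.5, 0.3, n)
        true_lfc = np.array([1.0] * 10 + [-1.0] * 10 + [0.0] * 180)
        cols = []
        for lfc in true_lfc:
            base = rng.uniform(5e-4, 5e-3)
            mu = s * base * np.where(cond == "aged", 2.0 ** lfc, 1.0)
            cols.append(rng.poisson(rng.gamma(1 / 0.2, mu * 0.2)))
        cm = matrix(np.array(cols).T)  # large null background keeps totals stable
        labels = pd.Series(cond, index=cm.cell_ids)
        means = condition_mean_cpm(cm, labels)
        est = np.log2((means["aged"] + 1) / (means["young"] + 1)).to_numpy()
        assert abs(est[:10].mean() - 1.0) < 0.15
        assert abs(est[10:20].mean() + 1.0) < 0.15


class TestCombinedDe:
    def test_bh_matches_oracle(self, rng):
        p = rng.random(200) ** 2
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_exon_only_equals_exonwise_bh(self, rng):
        X = rng.poisson(5.0, size=(60, 12))
        em = matrix(X, kind="exon",
                    features=[f"g{j}:1" for j in range(12)])
        labels = pd.Series(["a"] * 30 + ["b"] * 30, index=em.cell_ids)
        table = run_combined_de(None, em, labels, reference="a")
        assert (table["kind"] == "exon").all()
        np.testing.assert_allclose(table["fdr"], bh_oracle(table["p"]),
                                   atol=1e-12)
        assert table["dee_class"].isna().all()

    def test_combined_bh_spans_genes_and_exons(self, rng):
        Xg = rng.poisson(5.0, size=(60, 8))
        gm = matrix(Xg, kind="gene", features=[f"g{j}" for j in range(8)])
        Xe = rng.poisson(3.0, size=(60, 10))
        em = matrix(Xe, kind="exon",
                    features=[f"g{j % 8}:{j // 8 + 1}" for j in range(10)])
        labels = pd.Series(["a"] * 30 + ["b"] * 30, index=gm.cell_ids)
        table = run_combined_de(gm, em, labels, reference="a")
        assert len(table) == 18
        np.testing.assert_allclose(table["fdr"], bh_oracle(table["p"]), atol=1e-12)

    def test_permuted_labels_give_no_calls(self, small_study, rng):
        """Permuting condition labels destroys every planted effect."""
        gm = small_study["gene_matrix"]
        cells = small_study["cells"].set_index("cell_id")
        perm = rng.permutation(cells.loc[gm.cell_ids, "condition"].to_numpy())
        labels = pd.Series(perm, index=gm.cell_ids)
        table = run_combined_de(gm, None, labels, reference="young")
        assert table["is_DEG"].sum() <= 1

    def test_cell_set_mismatch_rejected(self, rng):
        gm = matrix(rng.poisson(5, (20, 3)), "gene")
        em = matrix(rng.poisson(5, (19, 3)), "exon",
                    features=["g0:1", "g1:1", "g2:1"])
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=gm.cell_ids)
        with pytest.raises(ValueError, match="share"):
            run_combined_de(gm, em, labels, reference="a")


class TestCallAndClassify:
    def _table(self, rows):
        cols = ["feature_id", "kind", "parent_gene", "p", "fdr", "max_cpm",
                "log2fc"]
        return pd.DataFrame(rows, columns=cols)

    def test_deg_derived_refilter_rule(self):
        """The key subtlety: the parent passes FDR/FC at the exon CPM cutoff
        (>10) while failing the gene cutoff (>25), so the exon is DEG-derived
        although the parent is not itself a DEG."""
        table = self._table([
            ("gA", "gene", "gA", 1e-4, 0.01, 12.0, 0.85),
            ("gA:1", "exon", "gA", 1e-4, 0.01, 11.0, 0.9),
        ])
        out = call_and_classify(table, DEConfig())
        gene, exon = out.iloc[0], out.iloc[1]
        assert not gene["is_DEG"]           # fails max CPM > 25
        assert exon["is_DEE"]
        assert exon["dee_class"] == "DEG-derived"

    def test_non_deg_derived_when_parent_not_significant(self):
        table = self._table([
            ("gA", "gene", "gA", 0.2, 0.2, 40.0, 0.9),
            ("gA:1", "exon", "gA", 1e-4, 0.01, 11.0, 0.9),
        ])
        out = call_and_classify(table, DEConfig())
        assert out.iloc[1]["dee_class"] == "non-DEG-derived"

    def test_no_feature_passes(self):
        table = self._table([
            ("gA", "gene", "gA", 0.5, 0.6, 100.0, 2.0),
            ("gA:1", "exon", "gA", 0.7, 0.7, 50.0, 2.0),
        ])
        out = call_and_classify(table, DEConfig())
        assert not out["is_DEG"].any() and not out["is_DEE"].any()
        assert out["dee_class"].isna().all()

    def test_fold_change_is_two_sided(self):
        table = self._table([
            ("gA", "gene", "gA", 1e-4, 0.01, 100.0, -0.9),
            ("gB", "gene", "gB", 1e-4, 0.01, 100.0, 0.3),
        ])
        out = call_and_classify(table, DEConfig())
        assert out.iloc[0]["is_DEG"]        # |FC| > 1.5 downward
        assert not out.iloc[1]["is_DEG"]    # 2^0.3 < 1.5

    def test_exon_without_parent_row_is_error(self):
        # gene rows exist, but not for this exon's parent
        table = self._table([
            ("gB", "gene", "gB", 0.5, 0.5, 100.0, 0.1),
            ("gA:1", "exon", "gA", 1e-4, 0.01, 11.0, 0.9)])
        with pytest.raises(ValueError, match="parent"):
            call_and_classify(table, DEConfig())


class TestSharedLogfc:
    def _flagged(self, ids, lfc):
        return pd.DataFrame({"feature_id": ids, "log2fc": lfc,
                             "is_DEG": [True] * len(ids)})

    def test_identical_vectors_r_one(self):
        a = self._flagged(["x", "y", "z"], [1.0, -0.5, 2.0])
        out = shared_logfc_correlation(a, a)
        assert out["r"] == pytest.approx(1.0)
        assert out["n_shared"] == 3

    def test_negated_vectors_r_minus_one(self):
        a = self._flagged(["x", "y", "z"], [1.0, -0.5, 2.0])
        b = self._flagged(["x", "y", "z"], [-1.0, 0.5, -2.0])
        assert shared_logfc_correlation(a, b)["r"] == pytest.approx(-1.0)

    def test_matches_scipy_oracle(self, rng):
        ids = [f"f{i}" for i in range(100)]
        x, y = rng.normal(size=100), rng.normal(size=100)
        out = shared_logfc_correlation(self._flagged(ids, x),
                                       self._flagged(ids, y))
        r, p = stats.pearsonr(x, y)
        assert out["r"] == pytest.approx(r, abs=1e-10)
        assert out["p"] == pytest.approx(p, abs=1e-10)

    def test_too_few_shared(self):
        a = self._flagged(["x"], [1.0])
        out = shared_logfc_correlation(a, a)
        assert out["r"] is None and out["n_shared"] == 1
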
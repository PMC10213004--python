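"""QC, normalization, rank-sum DE (exact and asymptotic), markers, concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import make_adata
from mirshift import singlecell as sc
from mirshift import synthetic as syn


def enumeration_ranksum_p(x, y) -> float:
    """Independent oracle: iterate every C(n+m, n) relabeling explicitly."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, N = len(x), len(pooled)
    w_obs = ranks[:n].sum()
    mean = n * (N + 1) / 2
    dev = abs(w_obs - mean)
    hits = total = 0
    for comb in itertools.combinations(range(N), n):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mean) >= dev - 1e-9:
            hits += 1
    return hits / total


class TestQC:
    def test_min_genes_boundary(self):
        counts = np.zeros((2, 600), dtype=int)
        counts[0, :499] = 1  # 499 expressed genes -> removed
        counts[1, :500] = 1  # exactly 500 -> retained
        obs = pd.DataFrame({"mito_frac": [0.0, 0.0], "doublet_score": [0.0, 0.0]},
                           index=["c0", "c1"])
        kept, report = sc.qc_filter(make_adata(counts, obs))
        assert list(kept.obs_names) == ["c1"]
        assert report["removed_min_genes"] == 1

    def test_mito_boundary(self):
        counts = np.ones((3, 600), dtype=int)
        obs = pd.DataFrame(
            {"mito_frac": [0.16, 0.15, 0.14], "doublet_score": [0.0] * 3},
            index=["a", "b", "c"],
        )
        kept, report = sc.qc_filter(make_adata(counts, obs))
        assert list(kept.obs_names) == ["b", "c"]  # rule is strictly greater

    def test_doublet_boundary_and_missing_column(self):
        counts = np.ones((2, 600), dtype=int)
        obs = pd.DataFrame({"mito_frac": [0.0, 0.0], "doublet_score": [0.26, 0.25]},
                           index=["a", "b"])
        kept, _ = sc.qc_filter(make_adata(counts, obs))
        assert list(kept.obs_names) == ["b"]
        with pytest.warns(UserWarning, match="doublet"):
            sc.qc_filter(make_adata(counts, pd.DataFrame({"mito_frac": [0.0, 0.0]},
                                                         index=["a", "b"])))
        with pytest.raises(ValueError):
            sc.qc_filter(
                make_adata(counts, pd.DataFrame({"mito_frac": [0.0, 0.0]},
                                                index=["a", "b"])),
                strict=True,
            )

    def test_planted_violations_recovered_exactly(self):
        """Cells constructed to violate specific rules are exactly the
        removed set."""
        rng = np.random.default_rng(0)
        counts = rng.poisson(2, size=(30, 700))
        obs = pd.DataFrame(
            {
                "mito_frac": rng.uniform(0, 0.1, 30),
                "doublet_score": rng.uniform(0, 0.2, 30),
            },
            index=[f"c{i}" for i in range(30)],
        )
        bad = {"c3": "genes", "c11": "mito", "c19": "doublet"}
        counts[3] = 0
        counts[3, :100] = 1
        obs.loc["c11", "mito_frac"] = 0.5
        obs.loc["c19", "doublet_score"] = 0.9
        kept, report = sc.qc_filter(make_adata(counts, obs))
        assert set(obs.index) - set(kept.obs_names) == set(bad)
        assert report["n_removed"] == 3

    def test_mito_computed_from_gene_prefix(self):
        counts = np.ones((1, 600), dtype=int)
        genes = [f"mt-{j}" if j < 120 else f"g{j}" for j in range(600)]
        kept, _ = sc.qc_filter(make_adata(counts, genes=genes))  # 20% mito
        assert kept.n_obs == 0


class TestNormalize:
    def test_closed_form_value(self):
        """Cell total 2500, gene count 25 -> scaled 100 -> ln(101)."""
        counts = np.zeros((1, 100), dtype=int)
        counts[0, 0] = 25
        counts[0, 1:] = 25  # total 2500
        norm = sc.normalize(make_adata(counts))
        x = norm.X.toarray()
        assert x[0, 0] == pytest.approx(np.log(101.0), abs=1e-9)

    def test_all_zero_gene_stays_zero(self):
        counts = np.ones((3, 10), dtype=int)
        counts[:, 4] = 0
        norm = sc.normalize(make_adata(counts))
        assert np.all(norm.X.toarray()[:, 4] == 0)

    def test_expm1_identity(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3, size=(20, 200)) + (np.arange(200) == 0)
        norm = sc.normalize(make_adata(counts))
        sums = np.expm1(norm.X.toarray()).sum(axis=1)
        assert np.allclose(sums, 1e4, rtol=1e-9)

    def test_zero_count_cell_rejected(self):
        counts = np.zeros((1, 5), dtype=int)
        with pytest.raises(ValueError, match="zero-count"):
            sc.normalize(make_adata(counts))


class TestExactRankSum:
    def test_textbook_separated_groups(self):
        """{1,2,3} vs {4,5,6}: 2 of the 20 labelings are as extreme, p=0.1."""
        assert sc.exact_ranksum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_matches_enumeration_oracle_small_groups(self):
        """DP distribution == explicit enumeration for 200 random instances
        with both group sizes <= 7, including heavy ties."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n, m = rng.integers(2, 8, size=2)
            if rng.random() < 0.5:  # tied integer data half the time
                x = rng.integers(0, 4, n).astype(float)
                y = rng.integers(0, 4, m).astype(float)
            else:
                x = rng.normal(size=n)
                y = rng.normal(size=m)
            assert sc.exact_ranksum_p(x, y) == pytest.approx(
                enumeration_ranksum_p(x, y), abs=1e-12
            )

    def test_identical_groups(self):
        assert sc.exact_ranksum_p([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0


class TestWilcoxonDE:
    def _two_group_adata(self, a, b, obs_extra=None):
        counts = np.vstack([a, b]).astype(int)
        obs = pd.DataFrame(
            {
                "condition": ["A"] * len(a) + ["B"] * len(b),
                "cell_type": "MG",
            },
            index=[f"c{i}" for i in range(len(a) + len(b))],
        )
        adata = make_adata(counts, obs)
        return sc.normalize(adata)

    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        block = rng.poisson(5, size=(4, 50)) + 1
        adata = self._two_group_adata(block, block)
        de = sc.wilcoxon_de(adata, "MG", ("A", "B"))
        assert np.allclose(de["logFC"], 0)
        assert np.allclose(de["p"], 1)

    def test_bonferroni_multiplication(self):
        assert np.allclose(sc._adjust(np.array([0.01]), "bonferroni", m=5), 0.05)

    def test_symmetry_of_contrast(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(4, size=(8, 60)) + 1
        b = rng.poisson(6, size=(9, 60)) + 1
        adata = self._two_group_adata(a, b)
        d1 = sc.wilcoxon_de(adata, "MG", ("A", "B"))
        d2 = sc.wilcoxon_de(adata, "MG", ("B", "A"))
        assert np.allclose(d1["logFC"], -d2["logFC"])
        assert np.allclose(d1["p"], d2["p"])

    def test_too_few_cells_warns_empty(self):
        a = np.ones((2, 30)) * 3
        b = np.ones((4, 30)) * 3
        adata = self._two_group_adata(a, b)
        with pytest.warns(UserWarning, match="fewer than"):
            de = sc.wilcoxon_de(adata, "MG", ("A", "B"))
        assert de.empty

    def test_permutation_null_calibration(self):
        """Shuffled condition labels give ~5% of genes at raw p<0.05."""
        cfg = syn.SimConfig(seed=9, n_genes=2000, n_cells_per_condition=80)
        truth = syn.choose_targets(cfg)
        counts, meta = syn.gen_sc(cfg, truth, "CTRL")
        rng = np.random.default_rng(0)
        meta["condition"] = rng.permutation(["A"] * 40 + ["B"] * 40)
        adata = make_adata(counts.toarray(), meta, genes=cfg.genes)
        adata = sc.normalize(adata)
        de = sc.wilcoxon_de(adata, "MG", ("A", "B"))
        frac = (de["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.015

    def test_planted_target_shift_detected(self, sc_bundle, small_truth, small_cfg):
        de = sc.wilcoxon_de(sc_bundle, "MG", ("KD", "CTRL"))
        targets = [g for g in small_truth.true_target_ids if g in de.index]
        assert np.median(de.loc[targets, "logFC"]) > 0.4
        assert (de.loc[targets, "p_adj"] < 0.05).mean() > 0.5


class TestFindMarkers:
    def test_planted_programs_recovered(self, sc_bundle, small_truth):
        markers = sc.find_markers(sc_bundle, cluster_key="state")
        for state, program in small_truth.state_programs.items():
            found = set(markers.loc[(markers["cluster"] == state) & markers["is_marker"], "gene"])
            recall = len(found & set(program)) / len(program)
            assert recall >= 0.9, (state, recall)

    def test_screen_vs_marker_thresholds(self):
        """A gene at logFC ~0.4 passes the 0.25 screen but is not a marker."""
        rng = np.random.default_rng(2)
        base = rng.poisson(20, size=(40, 30))
        counts = base.copy()
        counts[:20, 0] = rng.poisson(20 * np.exp(0.4) * 1.07, size=20)  # ~0.4 in log
        obs = pd.DataFrame({"state": ["s1"] * 20 + ["s2"] * 20},
                           index=[f"c{i}" for i in range(40)])
        adata = sc.normalize(make_adata(counts, obs))
        markers = sc.find_markers(adata, cluster_key="state")
        row = markers[(markers["cluster"] == "s1") & (markers["gene"] == "g0")]
        if not row.empty:  # screened in
            assert 0.25 < row["logFC"].iloc[0]
            assert not row["is_marker"].iloc[0] or row["logFC"].iloc[0] > 0.5

    def test_shuffled_labels_give_no_markers(self, sc_bundle):
        rng = np.random.default_rng(5)
        shuffled = sc_bundle.copy()
        shuffled.obs["state"] = rng.permutation(shuffled.obs["state"].to_numpy())
        markers = sc.find_markers(shuffled, cluster_key="state")
        n_sig = int(markers["is_marker"].sum()) if not markers.empty else 0
        assert n_sig <= 2  # chance-level leakage only

    def test_singleton_cluster_skipped(self):
        counts = np.random.default_rng(0).poisson(5, (10, 20)) + 1
        obs = pd.DataFrame({"state": ["a"] * 9 + ["b"]},
                           index=[f"c{i}" for i in range(10)])
        adata = sc.normalize(make_adata(counts, obs))
        with pytest.warns(UserWarning, match="skipped"):
            sc.find_markers(adata, cluster_key="state")


class TestPseudobulkCorr:
    def test_identical_and_negated_vectors(self):
        a = pd.DataFrame({"logFC": [0.1, -0.5, 1.2, 0.3]}, index=list("abcd"))
        assert sc.pseudobulk_corr(a, a)["r"] == pytest.approx(1.0)
        neg = a * -1
        assert sc.pseudobulk_corr(a, neg)["r"] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=50), rng.normal(size=50)
        a = pd.DataFrame({"logFC": x}, index=[f"g{i}" for i in range(50)])
        b = pd.DataFrame({"logFC": y}, index=[f"g{i}" for i in range(50)])
        r = sc.pseudobulk_corr(a, b)["r"]
        want = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(want, abs=1e-12)

    def test_few_pairs_is_nan(self):
        a = pd.DataFrame({"logFC": [1.0]}, index=["g1"])
        with pytest.warns(UserWarning, match="shared pairs"):
            out = sc.pseudobulk_corr(a, a)
        assert np.isnan(out["r"])
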
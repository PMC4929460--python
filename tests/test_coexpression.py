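"""Network construction and module detection: closed forms, oracles, recovery."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import cnvindex as cx
from cnvindex import coexpression as co
from cnvindex.synthetic import ProteinMatrix


def protein_matrix(values, prenatal=0):
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    periods = ["prenatal"] * prenatal + ["adult"] * (values.shape[1] - prenatal)
    tissues = [f"t{j}" for j in range(values.shape[1])]
    return ProteinMatrix(
        values=pd.DataFrame(values, index=genes, columns=tissues),
        tissue_meta=pd.DataFrame({"tissue_id": tissues, "period": periods}))


def block_diss(sizes, within=0.1, between=0.9):
    n = sum(sizes)
    d = np.full((n, n), between)
    off = 0
    for s in sizes:
        d[off:off + s, off:off + s] = within
        off += s
    np.fill_diagonal(d, 0.0)
    genes = [f"g{i}" for i in range(n)]
    return pd.DataFrame(d, index=genes, columns=genes)


class TestFilterRareProteins:
    def test_ninety_percent_rule_boundary(self):
        # 24 tissues: 22 zeros (91.7%) dropped, 21 zeros (87.5%) kept
        row_dropped = [0.0] * 22 + [5.0, 5.0]
        row_kept = [0.0] * 21 + [5.0, 5.0, 5.0]
        mat = protein_matrix([row_dropped, row_kept])
        out = co.filter_rare_proteins(mat)
        assert list(out.values.index) == ["g1"]

    def test_all_nonzero_identity(self):
        mat = protein_matrix(np.ones((3, 24)))
        assert co.filter_rare_proteins(mat).values.shape == (3, 24)

    def test_cut_one_drops_only_all_zero(self):
        mat = protein_matrix([[0.0] * 24, [0.0] * 23 + [1.0]])
        out = co.filter_rare_proteins(mat, co.WgcnaConfig(zero_fraction_cut=1.0))
        assert list(out.values.index) == ["g1"]

    def test_all_dropped_raises(self):
        mat = protein_matrix(np.zeros((2, 24)))
        with pytest.raises(ValueError):
            co.filter_rare_proteins(mat)


class TestSignedAdjacency:
    def test_closed_forms_at_beta_18(self):
        t = np.arange(6, dtype=float)
        anti = -t
        # symmetric about the midpoint -> exactly orthogonal to the
        # antisymmetric centred ramp, so cor(t, ortho) = 0
        ortho = np.array([1.0, -1, 0, 0, -1, 1])
        values = pd.DataFrame([t, 2 * t + 3, anti, ortho],
                              index=list("abcd"), columns=[f"s{i}" for i in range(6)])
        adj = co.signed_adjacency(values, beta=18.0)
        assert adj.loc["a", "b"] == pytest.approx(1.0)          # cor +1
        assert adj.loc["a", "c"] == pytest.approx(0.0, abs=1e-12)  # cor -1
        assert adj.loc["a", "d"] == pytest.approx(0.5 ** 18)    # cor 0

    def test_range_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.lognormal(size=(20, 10)))
        adj = co.signed_adjacency(values, beta=6).to_numpy()
        assert adj.min() >= 0 and adj.max() <= 1
        assert np.allclose(adj, adj.T)
        assert (np.diag(adj) == 0).all()

    def test_monotone_nonincreasing_in_beta(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.normal(size=(15, 12)))
        a1 = co.signed_adjacency(values, beta=6).to_numpy()
        a2 = co.signed_adjacency(values, beta=12).to_numpy()
        assert (a2 <= a1 + 1e-12).all()

    def test_too_few_tissues_raises(self):
        with pytest.raises(ValueError):
            co.signed_adjacency(pd.DataFrame(np.ones((4, 2))), beta=6)


class TestTopologicalOverlap:
    def test_two_node_hand_value(self):
        adj = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        tom = co.topological_overlap(adj)
        assert tom.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_adjacency(self):
        adj = pd.DataFrame(np.zeros((4, 4)))
        tom = co.topological_overlap(adj).to_numpy()
        assert (tom[~np.eye(4, dtype=bool)] == 0).all()
        assert (np.diag(tom) == 1).all()

    @pytest.mark.parametrize("n", [6, 10])
    def test_matches_triple_loop_bruteforce(self, n):
        rng = np.random.default_rng(n)
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = co.topological_overlap(pd.DataFrame(a)).to_numpy()
        k = a.sum(axis=1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                # u in {i, j} contributes zero because the diagonal is zero
                expected = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert abs(tom[i, j] - expected) < 1e-12

    def test_asymmetric_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            co.topological_overlap(pd.DataFrame(a))


class TestClusterAverageLinkage:
    def test_two_points_single_merge(self):
        d = pd.DataFrame([[0.0, 0.3], [0.3, 0.0]])
        link = co.cluster_average_linkage(d)
        assert link.shape == (1, 4)
        assert link[0, 2] == pytest.approx(0.3)

    def test_blocks_join_last(self):
        d = block_diss([5, 5])
        link = co.cluster_average_linkage(d)
        assert link[-1, 2] == pytest.approx(0.9)
        assert link[-2, 2] == pytest.approx(0.1)

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(9)
        x = rng.random((12, 12))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        link = co.cluster_average_linkage(pd.DataFrame(d))
        assert (np.diff(link[:, 2]) >= -1e-12).all()

    def test_nan_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            co.cluster_average_linkage(pd.DataFrame(d))


class TestCutDynamic:
    def test_two_planted_blocks_recovered(self):
        d = block_diss([50, 50])
        link = co.cluster_average_linkage(d)
        labels = co.cut_dynamic(link, d)
        assert set(labels) == {"M1", "M2"}
        assert labels.iloc[:50].nunique() == 1 and labels.iloc[50:].nunique() == 1

    def test_small_block_below_floor_unassigned(self):
        # a coherent block of 10 among 40 mutually distant genes
        d = block_diss([10, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1] + [1] * 19)
        link = co.cluster_average_linkage(d)
        labels = co.cut_dynamic(link, d)
        assert (labels == co.UNASSIGNED).all()

    def test_min_module_larger_than_n_raises(self):
        d = block_diss([4])
        link = co.cluster_average_linkage(d + 0.01 * (1 - np.eye(4)))
        with pytest.raises(ValueError):
            co.cut_dynamic(link, d, co.WgcnaConfig(min_module=10))

    def test_module_count_nondecreasing_in_deepsplit(self, proteome_5x50):
        counts = []
        for ds in (0, 2, 4):
            part = co.blockwise_modules(proteome_5x50, co.WgcnaConfig(deepsplit=ds))
            counts.append(len(part.modules))
        assert counts[0] <= counts[1] <= counts[2]


class TestModuleEigengenes:
    def test_identical_profiles_degenerate(self):
        base = np.array([1.0, 2, 3, 4, 5, 6])
        values = pd.DataFrame([base, base, base], index=list("abc"),
                              columns=[f"t{j}" for j in range(6)])
        labels = pd.Series(["M1"] * 3, index=list("abc"))
        eg, ve, kme = co.module_eigengenes(values, labels)
        assert ve["M1"] == pytest.approx(1.0)
        assert np.allclose(kme["M1"].to_numpy(), 1.0)
        assert np.linalg.norm(eg.loc["M1"]) == pytest.approx(1.0)

    def test_sign_anchor_under_global_negation(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.normal(size=(8, 10)))
        labels = pd.Series(["M1"] * 8, index=values.index)
        _, _, kme = co.module_eigengenes(values, labels)
        _, _, kme_neg = co.module_eigengenes(-values, labels)
        assert kme["M1"].mean() >= 0
        assert kme_neg["M1"].mean() >= 0

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.normal(size=(12, 9)))
        labels = pd.Series(["M1"] * 12, index=values.index)
        eg, ve, _ = co.module_eigengenes(values, labels)
        std = (values - values.mean(axis=1).values[:, None])
        std = std / std.std(axis=1, ddof=0).values[:, None]
        # brute-force principal direction from the tissue-space eigenproblem
        g = std.to_numpy().T @ std.to_numpy()
        w, v = np.linalg.eigh(g)
        principal = v[:, -1]
        got = eg.loc["M1"].to_numpy()
        assert min(np.linalg.norm(got - principal), np.linalg.norm(got + principal)) < 1e-8
        assert ve["M1"] == pytest.approx(w[-1] / w.sum(), abs=1e-8)


class TestTrimKme:
    def test_strong_member_kept_weak_unassigned(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=12)
        coherent = [base + 0.1 * rng.normal(size=12) for _ in range(30)]
        weak = rng.normal(size=12)  # uncorrelated profile
        values = pd.DataFrame(coherent + [weak])
        values.index = [f"g{i}" for i in range(31)]
        labels = pd.Series(["M1"] * 31, index=values.index)
        out = co.trim_kme(values, labels, co.WgcnaConfig(min_module=30))
        assert out["g30"] == co.UNASSIGNED
        assert (out[[f"g{i}" for i in range(30)]] == "M1").all()

    def test_module_dissolves_below_floor(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=12)
        coherent = [base + 0.1 * rng.normal(size=12) for _ in range(29)]
        weak = rng.normal(size=12)
        values = pd.DataFrame(coherent + [weak])
        values.index = [f"g{i}" for i in range(30)]
        labels = pd.Series(["M1"] * 30, index=values.index)
        out = co.trim_kme(values, labels, co.WgcnaConfig(min_module=30))
        assert (out == co.UNASSIGNED).all()


class TestMergeCloseModules:
    @staticmethod
    def two_module_matrix(target_cor, n_tissues=30, rng_seed=7):
        """Two noiseless modules whose factors correlate at exactly target_cor."""
        rng = np.random.default_rng(rng_seed)
        f1 = rng.normal(size=n_tissues)
        g = rng.normal(size=n_tissues)
        f1c = (f1 - f1.mean()) / np.linalg.norm(f1 - f1.mean())
        gc = g - g.mean()
        gc -= (gc @ f1c) * f1c
        gc /= np.linalg.norm(gc)
        f2 = target_cor * f1c + np.sqrt(1 - target_cor ** 2) * gc
        rows = [2.0 * f1c + i * 0.0 for i in range(3)] + [5.0 * f2 for _ in range(3)]
        values = pd.DataFrame(rows, index=[f"g{i}" for i in range(6)],
                              columns=[f"t{j}" for j in range(n_tissues)])
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=values.index)
        return values, labels

    def test_identical_eigengenes_merge(self):
        values, labels = self.two_module_matrix(1.0)
        part = co.merge_close_modules(values, labels, co.WgcnaConfig(min_module=1))
        assert len(part.modules) == 1

    def test_distant_modules_not_merged(self):
        values, labels = self.two_module_matrix(0.5)  # dissimilarity 0.5
        part = co.merge_close_modules(values, labels, co.WgcnaConfig(min_module=1))
        assert len(part.modules) == 2

    def test_boundary_is_strict_below_threshold(self):
        values, labels = self.two_module_matrix(0.66)  # dissimilarity 0.34 < 0.35
        part = co.merge_close_modules(values, labels, co.WgcnaConfig(min_module=1))
        assert len(part.modules) == 1
        values, labels = self.two_module_matrix(0.65)  # dissimilarity 0.35, not <
        part = co.merge_close_modules(values, labels, co.WgcnaConfig(min_module=1))
        assert len(part.modules) == 2


class TestSoftThreshold:
    def test_mean_connectivity_strictly_decreasing(self, proteome_5x50):
        tab = co.pick_soft_threshold(proteome_5x50, candidate_betas=[2, 6, 10, 14, 18])
        assert (np.diff(tab["mean_connectivity"]) < 0).all()

    def test_noise_matrix_not_scale_free_at_beta_1(self):
        cfg = cx.SimConfig(seed=3, n_genes=250, n_planted=50, within_module_cor=0.0)
        prot = cx.generate_all(cfg)["proteome"]
        tab = co.pick_soft_threshold(prot, candidate_betas=[1])
        assert tab["scale_free_r2"].iloc[0] < 0.8

    def test_degenerate_connectivity_reported_missing(self):
        values = np.tile(np.arange(6, dtype=float), (5, 1))  # identical profiles
        mat = protein_matrix(values + 1)
        tab = co.pick_soft_threshold(mat, candidate_betas=[2])
        assert np.isnan(tab["scale_free_r2"].iloc[0])


class TestBlockwiseModules:
    def test_equivalent_to_single_block_when_small(self, proteome_5x50):
        p_full = co.blockwise_modules(proteome_5x50, co.WgcnaConfig(max_block=20_000))
        p_also = co.blockwise_modules(proteome_5x50, co.WgcnaConfig(max_block=250))
        pd.testing.assert_series_equal(p_full.labels, p_also.labels)

    def test_small_blocks_agree_with_single_block(self):
        cfg = cx.SimConfig(seed=1, n_genes=500, n_planted=50)
        prot = cx.generate_all(cfg)["proteome"]
        p_full = co.blockwise_modules(prot, co.WgcnaConfig())
        p_blocked = co.blockwise_modules(prot, co.WgcnaConfig(max_block=200))
        common = p_full.labels.index
        ari = adjusted_rand_score(p_full.labels[common], p_blocked.labels[common])
        assert ari >= 0.8

    def test_deterministic(self, proteome_5x50):
        p1 = co.blockwise_modules(proteome_5x50)
        p2 = co.blockwise_modules(proteome_5x50)
        pd.testing.assert_series_equal(p1.labels, p2.labels)
        pd.testing.assert_frame_equal(p1.eigengenes, p2.eigengenes)

    def test_partition_invariants(self, proteome_5x50):
        part = co.blockwise_modules(proteome_5x50)
        assert (np.abs(part.kme.to_numpy()) <= 1 + 1e-12).all()
        norms = np.linalg.norm(part.eigengenes.to_numpy(), axis=1)
        assert np.allclose(norms, 1.0)
        assert (part.connectivity["kWithin"] <= part.connectivity["kTotal"] + 1e-9).all()


def test_planted_module_recovery_ari(proteome_5x50):
    """Full pipeline at published defaults recovers the 5x50 planted modules."""
    part = co.blockwise_modules(proteome_5x50, co.WgcnaConfig())
    truth = proteome_5x50.module_labels
    ari = adjusted_rand_score(truth.to_numpy(),
                              part.labels.reindex(truth.index).fillna("dropped").to_numpy())
    assert ari >= 0.8
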
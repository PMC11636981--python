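import numpy as np
import pandas as pd
import pytest

import networkx as nx

import ventnet.network as net


def _expr_df(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=genes,
                        columns=[f"s{j}" for j in range(arr.shape[1])])


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Independent triple-loop topological overlap."""
    n = a.shape[0]
    a = a.copy()
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (l + a[i, j]) / (min(ki, kj) + 1.0 - a[i, j])
    return out


def random_adjacency(rng, n):
    m = rng.uniform(0, 1, size=(n, n))
    a = (m + m.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


class TestSelectTopVariable:
    def test_full_selection_is_identity(self):
        rng = np.random.default_rng(0)
        y = _expr_df(rng.normal(size=(10, 6)))
        assert net.select_top_variable(y, n=10).equals(y)

    def test_constant_gene_never_beats_a_varying_gene(self):
        y = _expr_df(np.vstack([np.zeros(6), np.random.default_rng(1).normal(size=(5, 6))]))
        top = net.select_top_variable(y, n=5)
        assert "g0" not in top.index

    def test_toy_matrix_matches_hand_variance_ranking(self):
        rows = [np.arange(6) * s for s in range(10)]  # variance grows with s
        y = _expr_df(np.array(rows, dtype=float))
        top = net.select_top_variable(y, n=3)
        assert set(top.index) == {"g7", "g8", "g9"}

    def test_invalid_n_rejected(self):
        y = _expr_df(np.random.default_rng(2).normal(size=(4, 5)))
        with pytest.raises(ValueError):
            net.select_top_variable(y, n=0)
        with pytest.raises(ValueError):
            net.select_top_variable(y, n=5)


class TestSignedHybridAdjacency:
    def test_perfect_correlation_gives_unit_weight(self):
        y = _expr_df([[1, 2, 3, 4], [2, 4, 6, 8]])
        a = net.signed_hybrid_adjacency(y, beta=8)
        assert a[0, 1] == pytest.approx(1.0)

    def test_negative_correlation_is_zeroed(self):
        y = _expr_df([[1, 2, 3, 4], [4, 3, 2, 1]])
        a = net.signed_hybrid_adjacency(y, beta=8)
        assert a[0, 1] == 0.0

    def test_half_correlation_at_beta_eight(self):
        # orthogonal mean-zero noise scaled so Pearson r is exactly 0.5:
        # cor(x, x + c*e) = |x| / sqrt(|x|^2 + c^2 |e|^2) with x.e = 0
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        e = np.array([1.0, -1.0, -1.0, 1.0, 0.0, 0.0])
        c = np.sqrt(4.5)  # 6 / (6 + 4.5 * 4) = 0.25
        y = _expr_df([x, x + c * e])
        a = net.signed_hybrid_adjacency(y, beta=8)
        assert a[0, 1] == pytest.approx(0.5 ** 8, rel=1e-10)
        assert a[0, 1] == pytest.approx(0.00390625, rel=1e-9)

    def test_zero_variance_gene_named_in_error(self):
        y = _expr_df([[1, 1, 1, 1], [1, 2, 3, 4]])
        with pytest.raises(ValueError, match="g0"):
            net.signed_hybrid_adjacency(y, beta=8)

    def test_raising_beta_weakly_shrinks_every_edge(self):
        rng = np.random.default_rng(3)
        y = _expr_df(rng.normal(size=(15, 10)))
        a1 = net.signed_hybrid_adjacency(y, beta=2)
        a2 = net.signed_hybrid_adjacency(y, beta=6)
        off = ~np.eye(15, dtype=bool)
        assert (a2[off] <= a1[off] + 1e-12).all()


class TestScaleFreeFit:
    def test_power_law_topology_scores_high(self):
        g = nx.barabasi_albert_graph(2000, 1, seed=0)
        a = nx.to_numpy_array(g).astype(float)
        np.fill_diagonal(a, 1.0)
        r2, slope, _ = net.scale_free_fit(a)
        assert r2 > 0.9
        assert slope < 0

    def test_equal_connectivity_graph_is_degenerate(self):
        a = np.full((25, 25), 0.5)
        np.fill_diagonal(a, 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            net.scale_free_fit(a)

    def test_random_graph_scores_below_power_law(self):
        g_pl = nx.barabasi_albert_graph(2000, 1, seed=1)
        g_er = nx.gnp_random_graph(300, 0.05, seed=1)
        scores = []
        for g in (g_pl, g_er):
            a = nx.to_numpy_array(g).astype(float)
            np.fill_diagonal(a, 1.0)
            scores.append(net.scale_free_fit(a)[0])
        assert scores[1] < scores[0]


class TestPickSoftThreshold:
    def test_cut_below_attainable_range_returns_smallest_candidate(self, pipeline_result):
        # signed R^2 is always >= -1, so a cut of -1 passes every candidate
        sub = net.select_top_variable(pipeline_result.logexpr, n=200)
        beta, _ = net.pick_soft_threshold(sub, candidate_betas=(2, 4, 6),
                                          r2_cut=-1.0)
        assert beta == 2

    def test_returns_smallest_beta_meeting_cut_per_fit_table(self, pipeline_result):
        sub = net.select_top_variable(pipeline_result.logexpr, n=300)
        beta, table = net.pick_soft_threshold(sub, candidate_betas=tuple(range(1, 13)),
                                              r2_cut=0.8)
        passing = table[table["signed_r2"] >= 0.8]
        if len(passing):
            assert beta == passing["beta"].iloc[0]
            assert (table[table["beta"] < beta]["signed_r2"] < 0.8).all()
        else:
            assert beta == table.loc[table["signed_r2"].idxmax(), "beta"]

    def test_empty_candidates_rejected(self):
        y = _expr_df(np.random.default_rng(5).normal(size=(25, 8)))
        with pytest.raises(ValueError):
            net.pick_soft_threshold(y, candidate_betas=())


class TestTopologicalOverlap:
    def test_isolated_unit_pair_has_full_overlap(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 1.0
        tom = net.topological_overlap(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_no_edge_no_shared_neighbors_gives_zero(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 1.0
        a[2, 3] = a[3, 2] = 1.0
        tom = net.topological_overlap(a)
        assert tom[0, 2] == 0.0

    def test_matches_triple_loop_oracle_on_random_networks(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = int(rng.integers(5, 20))
            a = random_adjacency(rng, n)
            assert np.abs(net.topological_overlap(a) - tom_oracle(a)).max() < 1e-12

    def test_bounds_and_symmetry(self):
        a = random_adjacency(np.random.default_rng(8), 30)
        tom = net.topological_overlap(a)
        assert np.allclose(tom, tom.T)
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()
        assert np.allclose(np.diag(tom), 1.0)


class TestDetectModules:
    def test_two_planted_blocks_recovered_without_grey(self):
        # between-block dissimilarity must exceed the 0.99 static cut
        n = 80
        tom = np.zeros((n, n))
        tom[:40, :40] = 0.6
        tom[40:, 40:] = 0.6
        np.fill_diagonal(tom, 1.0)
        genes = [f"g{i}" for i in range(n)]
        part = net.detect_modules(tom, genes, min_module_size=30)
        assert len(part.modules) == 2
        assert (part.labels != "grey").all()
        assert part.labels.iloc[:40].nunique() == 1
        assert part.labels.iloc[40:].nunique() == 1

    def test_uniformly_similar_genes_form_single_module(self):
        n = 40
        tom = np.full((n, n), 0.9)
        np.fill_diagonal(tom, 1.0)
        part = net.detect_modules(tom, [f"g{i}" for i in range(n)], min_module_size=30)
        assert len(part.modules) == 1

    def test_min_module_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            net.detect_modules(np.eye(10), [f"g{i}" for i in range(10)],
                               min_module_size=1)

    def test_default_synthetic_modules_recovered(self, pipeline_result):
        from sklearn.metrics import adjusted_rand_score

        r = pipeline_result
        truth = pd.Series(r.truth.gene_module)
        ari = adjusted_rand_score(
            truth[r.partition.labels.index], r.partition.labels
        )
        assert ari >= 0.9


class TestModuleEigengenes:
    def test_identical_genes_give_their_standardized_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        y = _expr_df(np.tile(profile, (4, 1)))
        labels = pd.Series("blue", index=y.index)
        me = net.module_eigengenes(y, labels)["MEblue"].to_numpy()
        z = (profile - profile.mean()) / profile.std()
        z = z / np.linalg.norm(z)
        assert me == pytest.approx(z, abs=1e-10)

    def test_explains_most_variance_among_unit_vectors(self):
        rng = np.random.default_rng(9)
        y = _expr_df(rng.normal(size=(20, 8)))
        labels = pd.Series("blue", index=y.index)
        me = net.module_eigengenes(y, labels)["MEblue"].to_numpy()
        z = ((y.T - y.mean(axis=1)) / y.std(axis=1, ddof=0)).T.to_numpy()
        me_var = ((z @ me) ** 2).sum()
        for _ in range(50):
            v = rng.normal(size=8)
            v /= np.linalg.norm(v)
            assert ((z @ v) ** 2).sum() <= me_var + 1e-9

    def test_sign_aligned_with_module_mean(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=8)
        y = _expr_df(base + rng.normal(0, 0.1, size=(10, 8)))
        labels = pd.Series("red", index=y.index)
        me = net.module_eigengenes(y, labels)["MEred"]
        flipped = net.module_eigengenes(-y, labels)["MEred"]
        assert np.corrcoef(me, y.mean(axis=0))[0, 1] > 0
        assert np.corrcoef(flipped, (-y).mean(axis=0))[0, 1] > 0

    def test_unit_norm(self, pipeline_result):
        mes = pipeline_result.partition.eigengenes
        norms = np.linalg.norm(mes.to_numpy(), axis=0)
        assert norms == pytest.approx(1.0)


class TestMergeModules:
    @staticmethod
    def _partition_from(y, labels):
        return net.ModulePartition(labels=labels, eigengenes=pd.DataFrame())

    def test_highly_correlated_eigengenes_merge(self):
        rng = np.random.default_rng(11)
        shared = rng.normal(size=10)
        block_a = shared + rng.normal(0, 0.01, size=(20, 10))
        block_b = shared + rng.normal(0, 0.01, size=(20, 10))
        y = _expr_df(np.vstack([block_a, block_b]))
        labels = pd.Series(["blue"] * 20 + ["red"] * 20, index=y.index)
        merged = net.merge_modules(self._partition_from(y, labels), y)
        assert len(merged.modules) == 1
        assert merged.merge_history

    def test_orthogonal_eigengenes_do_not_merge(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        b -= a * (a @ b) / (a @ a)  # orthogonalize
        y = _expr_df(np.vstack([
            a + rng.normal(0, 0.01, size=(20, 10)),
            b + rng.normal(0, 0.01, size=(20, 10)),
        ]))
        labels = pd.Series(["blue"] * 20 + ["red"] * 20, index=y.index)
        merged = net.merge_modules(self._partition_from(y, labels), y)
        assert len(merged.modules) == 2

    def test_single_linkage_chains_merge_transitively(self):
        # A ~ B and B ~ C strongly, A ~ C weakly: single linkage joins all three
        rng = np.random.default_rng(13)
        u = rng.normal(size=12)
        v = rng.normal(size=12)
        v -= u * (u @ v) / (u @ u)
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        prof_a = u
        prof_b = np.sqrt(0.5) * u + np.sqrt(0.5) * v   # cor ~0.71 with both
        prof_c = v
        blocks = [p + rng.normal(0, 0.05, size=(20, 12)) for p in (prof_a, prof_b, prof_c)]
        y = _expr_df(np.vstack(blocks))
        labels = pd.Series(["blue"] * 20 + ["red"] * 20 + ["green"] * 20, index=y.index)
        merged = net.merge_modules(
            self._partition_from(y, labels), y, merge_height=0.35
        )
        assert len(merged.modules) == 1


class TestConditionStatistics:
    def test_eigengene_equal_to_condition_has_unit_correlation(self):
        cond = pd.Series([1.0, 0, 1, 0, 1, 0], index=[f"s{j}" for j in range(6)])
        mes = pd.DataFrame({"MEblue": cond.to_numpy()}, index=cond.index)
        r, p = net.module_trait_correlation(mes, cond.to_frame("sulfide"))
        assert r.loc["MEblue", "sulfide"] == pytest.approx(1.0)
        assert p.loc["MEblue", "sulfide"] < 1e-6

    def test_constant_condition_rejected(self):
        mes = pd.DataFrame({"MEblue": np.random.default_rng(0).normal(size=6)})
        cond = pd.DataFrame({"sulfide": np.ones(6)})
        with pytest.raises(ValueError, match="constant"):
            net.module_trait_correlation(mes, cond)

    def test_planted_module_has_strongest_sulfide_correlation(self, pipeline_result):
        r = pipeline_result
        target = r.module_trait_r["sulfide"].abs()
        best_me = target.idxmax()
        best_module = best_me[2:]
        genes_in_best = r.partition.labels[r.partition.labels == best_module].index
        truth_modules = {r.truth.gene_module[g] for g in genes_in_best}
        # strongest sulfide module must be one of the two planted sulfide modules
        assert truth_modules & {0, 4}

    def test_permutation_null_is_dominated_by_planted_signal(self, pipeline_result):
        rng = np.random.default_rng(14)
        r = pipeline_result
        cond = (r.design.set_index("sample")["sulfide"] == "replete").astype(float)
        observed = abs(np.corrcoef(
            r.partition.eigengenes[r.module_trait_r["sulfide"].abs().idxmax()],
            cond[r.partition.eigengenes.index],
        )[0, 1])
        null = []
        for _ in range(200):
            perm = rng.permutation(cond.to_numpy())
            cors = [
                abs(np.corrcoef(r.partition.eigengenes[c], perm)[0, 1])
                for c in r.partition.eigengenes.columns
            ]
            null.append(max(cors))
        assert observed > np.quantile(null, 0.95)

    def test_gene_equal_to_condition_has_unit_gs(self):
        cond = pd.Series([1.0, 0, 1, 0, 1, 0], index=[f"s{j}" for j in range(6)])
        y = pd.DataFrame([cond.to_numpy(), [3, 1, 4, 1, 5, 9.0]],
                         index=["g0", "g1"], columns=cond.index)
        gs = net.gene_significance(y, cond)
        assert gs.loc["g0", "gs"] == pytest.approx(1.0)

    def test_noise_gene_gs_is_small(self):
        rng = np.random.default_rng(15)
        cond = pd.Series(rng.integers(0, 2, 30).astype(float),
                         index=[f"s{j}" for j in range(30)])
        y = pd.DataFrame(rng.normal(size=(500, 30)), columns=cond.index,
                         index=[f"g{i}" for i in range(500)])
        gs = net.gene_significance(y, cond)
        assert (gs["gs"].abs() < 0.6).all()

    def test_planted_members_have_higher_gs_than_noise(self, pipeline_result):
        r = pipeline_result
        gs = r.gs["sulfide"]["gs"].abs()
        members = [g for g in gs.index if r.truth.gene_module[g] in (0, 4)]
        noise = [g for g in gs.index if r.truth.gene_module[g] == -1]
        assert gs[members].mean() > gs[noise].mean()

    def test_gene_identical_to_eigengene_has_unit_mm(self):
        rng = np.random.default_rng(16)
        me = rng.normal(size=8)
        mes = pd.DataFrame({"MEblue": me}, index=[f"s{j}" for j in range(8)])
        y = pd.DataFrame([me], index=["g0"], columns=mes.index)
        mm = net.module_membership(y, mes)
        assert mm.loc["g0", "MEblue"] == pytest.approx(1.0)

    def test_planted_members_have_high_own_module_mm(self, pipeline_result):
        r = pipeline_result
        own = []
        for g in r.mm.index:
            m = r.partition.labels[g]
            if m != "grey" and r.truth.gene_module[g] >= 0:
                own.append(abs(r.mm.loc[g, f"ME{m}"]))
        assert np.mean(own) > 0.8

    def test_foreign_module_mm_is_small_for_noise_genes(self, pipeline_result):
        r = pipeline_result
        noise = [g for g in r.mm.index if r.truth.gene_module[g] == -1]
        frac_small = (r.mm.loc[noise].abs() < 0.5).to_numpy().mean()
        assert frac_small > 0.95
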
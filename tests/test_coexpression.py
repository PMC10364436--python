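import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import cernet
from cernet import Config
from cernet.coexpression import (ModuleResult, adjacency_matrix, cut_modules,
                                 gene_significance_membership, module_eigengene,
                                 module_trait_and_keys, pick_soft_threshold,
                                 remove_outlier_samples, scale_free_fit,
                                 select_hub_genes, tom_similarity, trait_indicators)


def _expr(genes, samples, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(genes, samples)),
                        index=[f"g{i}" for i in range(genes)],
                        columns=[f"s{j}" for j in range(samples)])


def _block_expr(n_blocks=2, block=50, noise=0, samples=30, within=0.9, seed=0):
    """Planted blocks sharing a latent driver; extra independent noise genes."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    lam = np.sqrt(within)
    for b in range(n_blocks):
        driver = rng.normal(size=samples)
        for _ in range(block):
            rows.append(lam * driver + np.sqrt(1 - lam ** 2) * rng.normal(size=samples))
            labels.append(b + 1)
    for _ in range(noise):
        rows.append(rng.normal(size=samples))
        labels.append(0)
    expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                        columns=[f"s{j}" for j in range(samples)])
    return expr, np.array(labels)


class TestOutlierRemoval:
    def test_homogeneous_samples_untouched(self):
        expr = _expr(100, 20, seed=1)
        out, removed = remove_outlier_samples(expr)
        assert removed == []
        assert out.shape == expr.shape

    def test_inflated_sample_removed_and_idempotent(self):
        expr = _expr(100, 20, seed=2)
        expr["s5"] = expr["s5"] * 10 + 3
        out, removed = remove_outlier_samples(expr)
        assert removed == ["s5"]
        out2, removed2 = remove_outlier_samples(out)
        assert removed2 == []

    def test_mass_flagging_is_error(self):
        # a cut low enough to shatter the tree flags too many samples
        expr = _expr(50, 10, seed=3)
        with pytest.raises(ValueError, match="review"):
            remove_outlier_samples(expr, cut_height=1e-6)


class TestSoftThreshold:
    def test_power_one_adjacency_is_absolute_correlation(self):
        expr = _expr(5, 12, seed=4)
        adj = adjacency_matrix(expr, 1)
        r = np.abs(np.corrcoef(expr.to_numpy()))
        np.fill_diagonal(r, 0)
        assert np.allclose(adj.to_numpy(), r, atol=1e-12)

    def test_fit_index_matches_independent_binning(self):
        expr, _ = _block_expr(n_blocks=4, block=50, samples=30, seed=5)
        r = np.abs(np.corrcoef(expr.to_numpy()))
        np.fill_diagonal(r, 0.0)
        for beta in (2, 6, 10):
            k = np.sort((r ** beta).sum(axis=1))
            # independent re-binning: 10 equal-count chunks, density regression
            xs, ys = [], []
            for chunk in np.array_split(k, 10):
                w = chunk.max() - chunk.min()
                if w <= 0 or chunk.mean() <= 0:
                    continue
                xs.append(np.log10(chunk.mean()))
                ys.append(np.log10(len(chunk) / len(k) / w))
            slope, _, rv, _, _ = stats.linregress(xs, ys)
            expected = -np.sign(slope) * rv ** 2
            assert scale_free_fit(k) == pytest.approx(expected, abs=1e-8)

    def test_selection_stable_across_seeds(self):
        b1, _ = _block_expr(4, 50, noise=100, seed=6)
        b2, _ = _block_expr(4, 50, noise=100, seed=7)
        p1, t1 = pick_soft_threshold(b1)
        p2, _ = pick_soft_threshold(b2)
        assert abs(p1 - p2) <= 2
        assert set(t1.columns) >= {"power", "fit", "mean_k"}

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="8 samples"):
            pick_soft_threshold(_expr(10, 6))


class TestTOM:
    def test_complete_triangle(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = tom_similarity(a)
        # (l + a) / (min k + 1 - a) = (1 + 1) / (2 + 1 - 1) = 1
        off = tom[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_zero_adjacency(self):
        tom = tom_similarity(np.zeros((4, 4)))
        assert np.allclose(tom, np.eye(4))

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 1, (20, 20))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        tom = tom_similarity(a)
        n = len(a)
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                k_i = sum(a[i, u] for u in range(n) if u != i)
                k_j = sum(a[j, u] for u in range(n) if u != j)
                expected = (l + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 1, (40, 40))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        tom = tom_similarity(a)
        assert tom.min() >= 0 and tom.max() <= 1
        assert np.allclose(tom, tom.T)

    def test_asymmetric_input_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)


class TestCutModules:
    def test_two_planted_blocks_recovered_exactly(self):
        expr, truth = _block_expr(n_blocks=2, block=50, samples=40, seed=10)
        adj = adjacency_matrix(expr, 6)
        tom = tom_similarity(adj.to_numpy())
        labels = cut_modules(1 - tom, expr=expr, min_size=30)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert len(set(labels)) == 2

    def test_small_noise_clusters_unassigned(self):
        expr = _expr(20, 30, seed=11)
        adj = adjacency_matrix(expr, 6)
        tom = tom_similarity(adj.to_numpy())
        with pytest.warns(UserWarning, match="unassigned"):
            labels = cut_modules(1 - tom, expr=expr, min_size=30)
        assert (labels == 0).all()

    def test_duplicated_genes_share_labels(self):
        expr, _ = _block_expr(n_blocks=2, block=25, samples=30, seed=12)
        dup = pd.concat([expr, expr.add_suffix("_copy", axis=0)])
        adj = adjacency_matrix(dup, 6)
        tom = tom_similarity(adj.to_numpy())
        labels = pd.Series(cut_modules(1 - tom, expr=dup, min_size=30),
                           index=dup.index)
        for g in expr.index:
            assert labels[g] == labels[g + "_copy"]


class TestEigengene:
    def test_identical_genes_perfect_correlation(self):
        rng = np.random.default_rng(13)
        row = rng.normal(size=20)
        expr = pd.DataFrame([row] * 5, index=[f"g{i}" for i in range(5)],
                            columns=[f"s{j}" for j in range(20)])
        labels = pd.Series(1, index=expr.index)
        eig = module_eigengene(expr, labels)
        for g in expr.index:
            assert np.corrcoef(eig.loc[1], expr.loc[g])[0, 1] == pytest.approx(1.0)

    def test_sign_orientation_with_anticorrelated_members(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=30)
        expr = pd.DataFrame([x, -x, x, x], index=list("abcd"),
                            columns=[f"s{j}" for j in range(30)])
        eig = module_eigengene(expr, pd.Series(1, index=expr.index))
        cors = [np.corrcoef(eig.loc[1], expr.loc[g])[0, 1] for g in expr.index]
        assert np.mean(cors) >= 0

    def test_recovers_latent_driver(self):
        rng = np.random.default_rng(15)
        driver = rng.normal(size=30)
        rows = [0.9 * driver + 0.45 * rng.normal(size=30) for _ in range(50)]
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(50)],
                            columns=[f"s{j}" for j in range(30)])
        eig = module_eigengene(expr, pd.Series(1, index=expr.index))
        assert abs(np.corrcoef(eig.loc[1], driver)[0, 1]) >= 0.9

    def test_unit_variance(self):
        expr, _ = _block_expr(2, 30, samples=25, seed=16)
        labels = pd.Series([1] * 30 + [2] * 30, index=expr.index)
        eig = module_eigengene(expr, labels)
        assert np.allclose(eig.std(axis=1, ddof=1), 1.0)

    def test_largest_variance_share(self):
        """The eigengene matches the top right-singular vector's share."""
        expr, _ = _block_expr(1, 20, samples=15, seed=17)
        labels = pd.Series(1, index=expr.index)
        eig = module_eigengene(expr, labels).loc[1].to_numpy()
        z = stats.zscore(expr.to_numpy(), axis=1)
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        assert abs(np.corrcoef(eig, vt[0])[0, 1]) == pytest.approx(1.0, abs=1e-10)


def _samples_df(tps=(0, 12, 24, 48, 72), reps=6):
    return pd.DataFrame({
        "sample_id": [f"T{t:02d}_r{r}" for t in tps for r in range(1, reps + 1)],
        "time_point_hours": [t for t in tps for _ in range(reps)],
        "replicate": [r for _ in tps for r in range(1, reps + 1)],
    })


class TestModuleTraitAndGS:
    def test_indicator_eigengene_perfect_correlation(self):
        samples = _samples_df()
        traits = trait_indicators(samples, samples["sample_id"])
        eig = pd.DataFrame([traits.loc[12]], index=[1])
        r, p, keys = module_trait_and_keys(eig, samples)
        assert r.loc[1, 12] == pytest.approx(1.0)
        assert keys[12] == 1

    def test_orthogonal_eigengene_low_correlation(self):
        samples = _samples_df()
        n = len(samples)
        sig = np.tile([1.0, -1.0], n // 2)  # alternates within every time point
        eig = pd.DataFrame([sig], index=[1], columns=samples["sample_id"])
        r, _, _ = module_trait_and_keys(eig, samples)
        assert np.abs(r.to_numpy()).max() <= 0.05

    def test_gs_mm_match_direct_correlation(self):
        rng = np.random.default_rng(18)
        samples = _samples_df(reps=4)
        expr = pd.DataFrame(rng.normal(size=(10, len(samples))),
                            index=[f"g{i}" for i in range(10)],
                            columns=samples["sample_id"])
        eig = pd.DataFrame(rng.normal(size=(2, len(samples))), index=[1, 2],
                           columns=samples["sample_id"])
        gs, mm = gene_significance_membership(expr, eig, samples)
        traits = trait_indicators(samples, samples["sample_id"])
        for g in expr.index:
            for t in traits.index:
                assert gs.loc[g, t] == pytest.approx(
                    np.corrcoef(expr.loc[g], traits.loc[t])[0, 1], abs=1e-12)
            for m in (1, 2):
                assert mm.loc[g, m] == pytest.approx(
                    np.corrcoef(expr.loc[g], eig.loc[m])[0, 1], abs=1e-12)

    def test_gene_equal_to_eigengene_or_trait(self):
        samples = _samples_df(reps=3)
        traits = trait_indicators(samples, samples["sample_id"])
        eig = pd.DataFrame([np.linspace(-1, 1, len(samples))], index=[1],
                           columns=samples["sample_id"])
        expr = pd.DataFrame([eig.loc[1], traits.loc[48]], index=["ge", "gt"],
                            columns=samples["sample_id"])
        gs, mm = gene_significance_membership(expr, eig, samples)
        assert mm.loc["ge", 1] == pytest.approx(1.0)
        assert gs.loc["gt", 48] == pytest.approx(1.0)


def _manual_result(mm_value, gs_value, key_module=1):
    genes = pd.Index(["g0"])
    labels = pd.Series([key_module], index=genes)
    r = pd.DataFrame({0: [0.9]}, index=[key_module])
    return ModuleResult(
        labels=labels,
        eigengenes=pd.DataFrame(),
        module_trait_r=r, module_trait_p=r * 0 + 1e-5,
        key_modules={0: 1},
        gs=pd.DataFrame({0: [gs_value]}, index=genes),
        mm=pd.DataFrame({key_module: [mm_value]}, index=genes),
        hub_genes=pd.DataFrame(), soft_power=6, fit_table=pd.DataFrame(),
        removed_samples=[])


class TestHubSelection:
    def test_boundary_mm_excluded(self):
        hubs = select_hub_genes(_manual_result(mm_value=0.8, gs_value=0.9))
        assert len(hubs) == 0  # strict inequality

    def test_passing_gene_selected(self):
        hubs = select_hub_genes(_manual_result(mm_value=0.85, gs_value=0.6))
        assert list(hubs["gene_id"]) == ["g0"]

    def test_gene_outside_key_modules_excluded(self):
        result = _manual_result(mm_value=0.99, gs_value=0.99)
        result.labels[:] = 2  # not the key module
        result.mm.columns = [2]
        result.module_trait_r = pd.DataFrame({0: [0.9, 0.1]}, index=[1, 2])
        result.module_trait_p = result.module_trait_r * 0 + 1e-5
        hubs = select_hub_genes(result)
        assert len(hubs) == 0
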
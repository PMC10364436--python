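import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cernet
from cernet.diffexpr import (call_de, estimate_common_dispersion, fpkm,
                             nb_exact_test, tmm_factors, tpm)
from conftest import toy_count_matrix


class TestTPM:
    def test_single_feature_is_one_million(self):
        cm = toy_count_matrix([[7, 900]], lengths=[1234])
        out = tpm(cm)
        assert np.allclose(out.to_numpy(), 1e6)

    def test_length_ratio(self):
        cm = toy_count_matrix([[100], [100]], lengths=[1000, 2000])
        out = tpm(cm)
        assert np.isclose(out.iloc[0, 0] / out.iloc[1, 0], 2.0)

    def test_scale_invariance_per_sample(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 100, (10, 3))
        cm1 = toy_count_matrix(counts, lengths=list(rng.integers(500, 5000, 10)))
        doubled = counts.copy()
        doubled[:, 1] *= 2
        cm2 = toy_count_matrix(doubled, lengths=list(cm1.length))
        pd.testing.assert_frame_equal(tpm(cm1), tpm(cm2))

    def test_columns_sum_to_one_million(self, small_dataset):
        out = tpm(small_dataset["cm"])
        assert np.allclose(out.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_column_is_error(self):
        cm = toy_count_matrix([[0, 5]])
        with pytest.raises(ValueError, match="s0"):
            tpm(cm)


class TestFPKM:
    def test_direct_formula(self):
        # count 100, length 1000, library 1e6 -> 100
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 100
        counts[1, 0] = 1_000_000 - 100
        cm = toy_count_matrix(counts, lengths=[1000, 500])
        assert np.isclose(fpkm(cm).iloc[0, 0], 100.0)

    def test_zero_count_zero_fpkm(self):
        cm = toy_count_matrix([[0], [10]])
        assert fpkm(cm).iloc[0, 0] == 0.0

    def test_halving_length_doubles_fpkm(self):
        a = toy_count_matrix([[50], [50]], lengths=[2000, 2000])
        b = toy_count_matrix([[50], [50]], lengths=[1000, 2000])
        assert np.isclose(fpkm(b).iloc[0, 0], 2 * fpkm(a).iloc[0, 0])


def _tmm_oracle(counts: pd.DataFrame) -> pd.Series:
    """Independent step-by-step trace of the TMM recipe."""
    lib = counts.sum(axis=0).astype(float)
    cpm = counts / lib * 1e6
    uq = cpm.quantile(0.75)
    ref = (uq - uq.mean()).abs().idxmin()
    raw = {}
    for s in counts.columns:
        y, yr = counts[s].to_numpy(float), counts[ref].to_numpy(float)
        n, nr = lib[s], lib[ref]
        ok = (y > 0) & (yr > 0)
        y, yr = y[ok], yr[ok]
        m = np.log2((y / n) / (yr / nr))
        a = 0.5 * np.log2((y / n) * (yr / nr))
        if np.max(np.abs(m)) < 1e-6:
            raw[s] = 1.0
            continue
        keep = np.ones(len(m), dtype=bool)
        lo, hi = np.quantile(m, [0.3, 0.7])
        keep &= (m >= lo) & (m <= hi)
        lo, hi = np.quantile(a, [0.05, 0.95])
        keep &= (a >= lo) & (a <= hi)
        w = 1.0 / ((n - y[keep]) / (n * y[keep]) + (nr - yr[keep]) / (nr * yr[keep]))
        raw[s] = 2.0 ** (np.sum(w * m[keep]) / np.sum(w))
    f = pd.Series(raw)
    return f / np.exp(np.log(f).mean())


class TestTMM:
    def test_identical_samples_all_factors_one(self):
        cm = toy_count_matrix(np.tile([[10], [20], [30], [40]], (1, 4)))
        nf = tmm_factors(cm)
        assert np.allclose(nf["tmm_factor"], 1.0)

    def test_global_scaling_absorbed_by_library_size(self):
        rng = np.random.default_rng(3)
        base = rng.integers(5, 200, 10)
        cm = toy_count_matrix(np.column_stack([base, base * 2]))
        nf = tmm_factors(cm)
        assert np.allclose(nf["tmm_factor"], 1.0, atol=1e-9)

    def test_matches_independent_recipe_trace(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.integers(0, 500, (20, 4)),
                              columns=list("abcd"))
        nf = tmm_factors(counts).set_index("sample_id")["tmm_factor"]
        oracle = _tmm_oracle(counts)
        assert np.allclose(nf[oracle.index], oracle, atol=1e-8)

    def test_geometric_mean_is_one(self, small_dataset):
        nf = tmm_factors(small_dataset["cm"])
        assert np.isclose(np.exp(np.log(nf["tmm_factor"]).mean()), 1.0, atol=1e-9)


def _nb_test_oracle(sum_a, sum_b, n_a, n_b, phi) -> float:
    """Direct enumeration of the conditional split distribution."""
    total = sum_a + sum_b
    mu = total / (n_a + n_b)
    probs = []
    for s in range(total + 1):
        if phi == 0:
            pa = stats.poisson.pmf(s, n_a * mu)
            pb = stats.poisson.pmf(total - s, n_b * mu)
        else:
            q = 1 / (1 + mu * phi)
            pa = stats.nbinom.pmf(s, n_a / phi, q)
            pb = stats.nbinom.pmf(total - s, n_b / phi, q)
        probs.append(pa * pb)
    probs = np.array(probs) / np.sum(probs)
    obs = probs[sum_a]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


class TestNBExactTest:
    def test_symmetric_split_gives_p_one(self):
        for phi in (0.0, 0.1, 0.5):
            assert nb_exact_test([10], [10], phi) == pytest.approx(1.0)

    def test_poisson_limit_matches_binomial_test(self):
        p_nb = nb_exact_test([0], [20], 0.0)
        p_binom = stats.binomtest(0, 20, 0.5).pvalue
        assert p_nb == pytest.approx(p_binom, abs=1e-10)

    @pytest.mark.parametrize("sums,phi", [
        ((3, 17), 0.0), ((3, 17), 0.1), ((40, 80), 0.2),
        ((0, 60), 0.05), ((100, 100), 0.1),
    ])
    def test_matches_enumeration_oracle(self, sums, phi):
        sa, sb = sums
        p = nb_exact_test([sa / 2, sa / 2], [sb / 2, sb / 2], phi)
        assert p == pytest.approx(_nb_test_oracle(sa, sb, 2, 2, phi), abs=1e-10)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([1], [2], -0.1)

    def test_null_uniformity_conservative(self):
        """P(p <= alpha) stays near alpha for NB null data."""
        rng = np.random.default_rng(5)
        n_genes, n = 2000, 6
        mu = np.exp(rng.uniform(np.log(30), np.log(300), n_genes))
        lam = rng.gamma(10.0, 0.1 * mu[:, None], (n_genes, 2 * n))
        counts = rng.poisson(lam)
        ps = np.array([nb_exact_test(c[:n], c[n:], 0.1) for c in counts])
        for alpha in (0.01, 0.05, 0.1):
            rate = (ps <= alpha).mean()
            se = np.sqrt(alpha * (1 - alpha) / n_genes)
            assert rate <= alpha + 3 * se + 0.005
            assert rate >= alpha - 3 * se - 0.005


class TestDispersionEstimate:
    def _null_counts(self, phi, seed, n_genes=2000, n=6):
        rng = np.random.default_rng(seed)
        mu = np.exp(rng.uniform(np.log(30), np.log(300), n_genes))
        if phi == 0:
            counts = rng.poisson(np.tile(mu[:, None], (1, 2 * n)))
        else:
            lam = rng.gamma(1 / phi, phi * mu[:, None], (n_genes, 2 * n))
            counts = rng.poisson(lam)
        df = pd.DataFrame(counts, columns=[f"s{i}" for i in range(2 * n)])
        groups = {"a": [f"s{i}" for i in range(n)],
                  "b": [f"s{i}" for i in range(n, 2 * n)]}
        return df, groups

    @pytest.mark.parametrize("method", ["cml", "moments"])
    def test_poisson_truth_near_zero(self, method):
        df, groups = self._null_counts(0.0, 17)
        assert estimate_common_dispersion(df, groups, method=method) <= 0.01

    @pytest.mark.parametrize("method", ["cml", "moments"])
    def test_nb_truth_recovered(self, method):
        df, groups = self._null_counts(0.1, 23)
        est = estimate_common_dispersion(df, groups, method=method)
        assert 0.05 <= est <= 0.2

    def test_constant_matrix_zero(self):
        df = pd.DataFrame(np.full((50, 8), 20), columns=[f"s{i}" for i in range(8)])
        groups = {"a": [f"s{i}" for i in range(4)], "b": [f"s{i}" for i in range(4, 8)]}
        assert estimate_common_dispersion(df, groups) == 0.0

    def test_unreplicated_design_rejected(self):
        df = pd.DataFrame([[1, 2]], columns=["s0", "s1"])
        with pytest.raises(ValueError, match="dispersion"):
            estimate_common_dispersion(df, {"a": ["s0"], "b": ["s1"]})


def _two_group_samples(n=6):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(2 * n)],
        "time_point_hours": [0] * n + [12] * n,
        "replicate": list(range(1, n + 1)) * 2,
    })


class TestCallDE:
    def test_flat_feature_is_ns_everywhere(self):
        counts = np.full((30, 12), 50)
        cm = toy_count_matrix(counts)
        de = call_de(cm, _two_group_samples(), dispersion=0.1)
        assert (de["direction"] == "ns").all()
        assert not de["union_de"].any()

    def test_missing_baseline_group_rejected(self):
        samples = _two_group_samples()
        samples["time_point_hours"] = [12] * 6 + [24] * 6
        cm = toy_count_matrix(np.full((5, 12), 50))
        with pytest.raises(ValueError, match="0 h"):
            call_de(cm, samples, dispersion=0.1)

    def test_circ_threshold_is_p_only(self):
        # modest true fold change ~1.3: below the 1.5x rule, above log2(1)=0
        rng = np.random.default_rng(3)
        mu = np.tile(np.exp(rng.uniform(np.log(100), np.log(400), 80))[:, None],
                     (1, 12))
        mu[:10, 6:] *= 1.3  # only the first 10 genes shift
        counts = rng.poisson(mu)
        cm_m = toy_count_matrix(counts, rna_class="mRNA")
        cm_c = toy_count_matrix(counts, rna_class="circRNA")
        samples = _two_group_samples()
        de_m = call_de(cm_m, samples, dispersion=0.0)
        de_c = call_de(cm_c, samples, dispersion=0.0)
        shifted_m = de_m[de_m["feature_id"].isin([f"g{i}" for i in range(10)])]
        shifted_c = de_c[de_c["feature_id"].isin([f"g{i}" for i in range(10)])]
        assert (shifted_m["direction"] == "ns").all()
        assert (shifted_c["direction"] == "up").mean() > 0.5

    def test_power_on_planted_effect(self):
        """An up-planted gene (fc 2^1.5, n=6, phi=0.05) is flagged >= 90%."""
        rng = np.random.default_rng(8)
        flags = 0
        reps = 200
        for _ in range(reps):
            mu = np.exp(rng.uniform(np.log(30), np.log(300), 25))
            lam0 = rng.gamma(20.0, 0.05 * mu[:, None], (25, 12))
            counts = rng.poisson(lam0)
            lam1 = rng.gamma(20.0, 0.05 * mu[0] * 2 ** 1.5, 6)
            counts[0, 6:] = rng.poisson(lam1)
            cm = toy_count_matrix(counts)
            de = call_de(cm, _two_group_samples(), dispersion=0.05)
            row = de[(de["feature_id"] == "g0") & (de["contrast"] == 12)]
            flags += (row["direction"] == "up").iloc[0]
        assert flags / reps >= 0.9

    def test_union_flag_equals_union_of_contrast_calls(self, small_dataset):
        cm = cernet.filter_low_expression(small_dataset["cm"])
        de = call_de(cm, small_dataset["samples"], dispersion=0.1)
        by_contrast = set()
        for _, grp in de.groupby("contrast"):
            by_contrast |= set(grp.loc[grp["direction"] != "ns", "feature_id"])
        flagged = set(de.loc[de["union_de"], "feature_id"])
        assert flagged == by_contrast

    def test_direction_consistent_with_thresholds(self, small_dataset):
        cm = cernet.filter_low_expression(small_dataset["cm"])
        config = cernet.Config()
        de = call_de(cm, small_dataset["samples"], dispersion=0.1, config=config)
        thr = np.where(de["rna_class"] == "circRNA",
                       np.log2(config.fc_circ), np.log2(config.fc_lnc_mi_mrna))
        up = (de["log2fc"] > thr) & (de["p_value"] < config.p_de)
        down = (de["log2fc"] < -thr) & (de["p_value"] < config.p_de)
        assert ((de["direction"] == "up") == up).all()
        assert ((de["direction"] == "down") == down).all()
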
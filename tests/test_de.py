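"""Unit tests for the NB differential-expression core."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_force_bh
from atf6rg import de


def make_cm(counts, groups=("A", "B")):
    counts = np.asarray(counts)
    n = counts.shape[1]
    half = n // 2
    cols = [f"s{i}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "cell_type": "x",
            "genotype": [groups[0]] * half + [groups[1]] * (n - half),
            "condition": "vehicle",
            "passage": "EP",
            "replicate": list(range(half)) + list(range(n - half)),
        },
        index=pd.Index(cols, name="sample_id"),
    )
    cdf = pd.DataFrame(counts, index=[f"g{i}" for i in range(len(counts))], columns=cols)
    return de.CountMatrix(counts=cdf, samples=samples)


def simulate_nb(n_genes, n_per_group, dispersion, lfc=0.0, seed=0, mu_median=100.0):
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(mu_median), 1.2, n_genes)
    m = np.repeat(mu[:, None], 2 * n_per_group, axis=1)
    m[:, :n_per_group] *= 2.0**lfc
    k = rng.negative_binomial(1 / dispersion, 1 / (1 + dispersion * m))
    return make_cm(k)


AB = de.Contrast("A_vs_B", {"genotype": "A"}, {"genotype": "B"})
BA = de.Contrast("B_vs_A", {"genotype": "B"}, {"genotype": "A"})


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5], "c": [10, 20, 5]})
        assert np.allclose(de.size_factors(counts), 1.0)

    def test_doubled_column_closed_form(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        sf = de.size_factors(counts)
        assert np.allclose(sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)])

    def test_single_sample_is_one(self):
        counts = pd.DataFrame({"a": [3, 7]})
        assert de.size_factors(counts).tolist() == [1.0]

    def test_geometric_mean_is_one_and_scaling_covariance(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.poisson(50, (200, 5)) + 1)
        sf = de.size_factors(counts)
        assert abs(np.log(sf).mean()) < 1e-12
        scaled = counts.copy()
        scaled[3] = counts[3] * 4
        sf2 = de.size_factors(scaled)
        # scaling one column by c scales its factor by c (up to the global rescale)
        ratio = sf2 / sf
        assert np.allclose(ratio[3] / ratio[0], 4.0)

    def test_no_reference_gene_raises(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            de.size_factors(counts)


class TestDispersion:
    def test_poisson_data_near_floor(self):
        cm = simulate_nb(1000, 3, 1e-12, seed=1)  # effectively Poisson
        sf = de.size_factors(cm.counts)
        disp = de.estimate_dispersions(cm.counts, sf, cm.samples["genotype"])
        assert disp.median() < 1e-3

    def test_recovers_true_dispersion_at_n6(self):
        cm = simulate_nb(1000, 6, 0.1, seed=2)
        sf = de.size_factors(cm.counts)
        disp = de.estimate_dispersions(cm.counts, sf, cm.samples["genotype"])
        assert 0.05 <= disp.median() <= 0.2

    def test_common_dispersion_near_truth(self):
        cm = simulate_nb(2000, 3, 0.05, seed=3)
        sf = de.size_factors(cm.counts)
        a = de.common_dispersion(cm.counts, sf, cm.samples["genotype"])
        assert 0.035 <= a <= 0.065

    def test_constant_gene_gets_floor(self):
        counts = pd.DataFrame(
            np.vstack([np.full(6, 50), np.random.default_rng(0).poisson(100, 6)])
        )
        sf = pd.Series(1.0, index=counts.columns)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        disp = de.estimate_dispersions(counts, sf, groups, shrink_weight=0.0)
        assert disp.iloc[0] == pytest.approx(de.DISPERSION_FLOOR)

    def test_singleton_groups_raise(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        sf = pd.Series(1.0, index=counts.columns)
        groups = pd.Series(["A", "B"], index=counts.columns)
        with pytest.raises(ValueError, match="replicate group"):
            de.estimate_dispersions(counts, sf, groups)


class TestWald:
    def test_identical_groups_give_zero_lfc_unit_p(self):
        block = np.array([[10, 20, 30], [5, 0, 7], [100, 90, 110]])
        cm = make_cm(np.hstack([block, block]))
        res = de.nb_wald_contrast(cm, AB)
        tested = res[res["tested"]]
        assert np.allclose(tested["log2FoldChange"], 0.0)
        assert np.allclose(tested["pvalue"], 1.0)

    def test_group_label_swap_negates_lfc_keeps_p(self):
        cm = simulate_nb(300, 3, 0.05, lfc=1.0, seed=5)
        r1 = de.nb_wald_contrast(cm, AB)
        r2 = de.nb_wald_contrast(cm, BA)
        t = r1["tested"] & r2["tested"]
        assert np.allclose(
            r1.loc[t, "log2FoldChange"], -r2.loc[t, "log2FoldChange"]
        )
        assert np.allclose(r1.loc[t, "pvalue"], r2.loc[t, "pvalue"])

    def test_planted_lfc_recovered(self):
        # unit size factors: with the effect planted in every gene,
        # median-of-ratios would (correctly) absorb it as normalization
        cm = simulate_nb(400, 3, 0.05, lfc=-1.5, seed=6)
        disp = pd.Series(0.05, index=cm.counts.index)
        sf = pd.Series(1.0, index=cm.counts.columns)
        res = de.nb_wald_contrast(cm, AB, sf=sf, dispersions=disp)
        est = res.loc[res["tested"], "log2FoldChange"]
        assert abs(est.mean() + 1.5) < 0.15

    def test_zero_group_total_flagged_untested(self):
        cm = make_cm([[0, 0, 0, 5, 6, 7], [0, 0, 0, 0, 0, 0], [9, 9, 9, 9, 9, 9]])
        res = de.nb_wald_contrast(cm, AB)
        assert not res["tested"].iloc[0]
        assert not res["tested"].iloc[1]
        assert res["tested"].iloc[2]
        assert np.isnan(res["pvalue"].iloc[0])

    def test_matches_statsmodels_nb_glm(self):
        """With unit size factors the group-mean Wald test coincides with a
        statsmodels NB GLM fit at the same fixed dispersion."""
        sm = pytest.importorskip("statsmodels.api")
        alpha = 0.08
        cm = simulate_nb(20, 4, alpha, lfc=0.7, seed=7)
        disp = pd.Series(alpha, index=cm.counts.index)
        sf = pd.Series(1.0, index=cm.counts.columns)
        res = de.nb_wald_contrast(cm, AB, sf=sf, dispersions=disp)
        X = np.column_stack([np.ones(8), [1] * 4 + [0] * 4])
        for gene in cm.counts.index[:10]:
            y = cm.counts.loc[gene].to_numpy()
            if (y[:4].sum() == 0) or (y[4:].sum() == 0):
                continue
            glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
            lfc_glm = glm.params[1] / np.log(2)
            se_glm = glm.bse[1] / np.log(2)
            assert res.loc[gene, "log2FoldChange"] == pytest.approx(lfc_glm, abs=1e-5)
            assert res.loc[gene, "lfcSE"] == pytest.approx(se_glm, rel=1e-4)

    def test_null_pvalues_roughly_uniform(self):
        from scipy import stats

        cm = simulate_nb(2000, 3, 0.05, seed=8)
        disp = pd.Series(0.05, index=cm.counts.index)
        res = de.nb_wald_contrast(cm, AB, dispersions=disp)
        p = res["pvalue"].dropna().to_numpy()
        ks = stats.ks_1samp(p, stats.uniform.cdf).statistic
        assert ks < 0.05


class TestBH:
    def test_hand_computed_example(self):
        q = de.adjust_bh(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones_and_singleton(self):
        assert np.allclose(de.adjust_bh(np.ones(5)), 1.0)
        assert de.adjust_bh(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_nan_excluded_from_m(self):
        q = de.adjust_bh(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], [0.02, 0.04])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_matches_definitional_oracle(self, pvals):
        p = np.array(pvals)
        assert np.allclose(de.adjust_bh(p), brute_force_bh(p))

    def test_q_geq_p_and_monotone(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=500)
        q = de.adjust_bh(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDegCallsAndFpkm:
    def test_empty_result_empty_sets(self):
        res = pd.DataFrame(
            columns=["baseMean", "log2FoldChange", "lfcSE", "pvalue", "padj", "tested"]
        )
        up, down = de.call_degs(res)
        assert up == set() and down == set()

    def test_direction_assignment(self):
        res = pd.DataFrame(
            {
                "log2FoldChange": [2.0, -2.0, 0.5],
                "padj": [0.01, 0.01, 0.01],
                "tested": True,
            },
            index=["up", "down", "small"],
        )
        up, down = de.call_degs(res, alpha=0.05, lfc_min=1.0)
        assert up == {"up"} and down == {"down"}

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(12)
        res = pd.DataFrame(
            {
                "log2FoldChange": rng.normal(0, 2, 300),
                "padj": rng.uniform(size=300),
                "tested": rng.random(300) > 0.1,
            },
            index=[f"g{i}" for i in range(300)],
        )
        up, down = de.call_degs(res, alpha=0.1, lfc_min=0.5)
        for g in res.index:
            row = res.loc[g]
            expect_up = bool(row["tested"] and row["padj"] < 0.1 and row["log2FoldChange"] >= 0.5)
            expect_down = bool(row["tested"] and row["padj"] < 0.1 and row["log2FoldChange"] <= -0.5)
            assert (g in up) == expect_up
            assert (g in down) == expect_down
        assert not (up & down)

    def test_fpkm_arithmetic_and_invariances(self):
        counts = pd.DataFrame({"s": [100, 0]}, index=["a", "b"])
        counts.loc["filler"] = [10_000_000 - 100]
        lengths = pd.Series([1000, 500, 1000], index=["a", "b", "filler"])
        out = de.fpkm(counts, lengths)
        assert out.loc["a", "s"] == pytest.approx(10.0)
        assert out.loc["b", "s"] == 0.0
        doubled = de.fpkm(counts * 2, lengths)
        assert np.allclose(out, doubled)

    def test_fpkm_zero_library_raises(self):
        counts = pd.DataFrame({"s": [0, 0]})
        with pytest.raises(ValueError, match="zero library"):
            de.fpkm(counts, pd.Series([100, 100]))
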
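"""Consensus calling, magnitude binning and the X-distribution permutation test."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from dosagecomp import (SimConfig, bin_by_magnitude, consensus_calls,
                        internal_de_test, permutation_distribution_test,
                        simulate_counts, simulate_genome,
                        smallest_significant_threshold, threshold_sweep)

from .oracles import hypergeom_upper_tail_exact


def call_table(method, calls):
    """calls: list of (gene, significant, direction)."""
    return pd.DataFrame({
        "method": method,
        "gene": [g for g, _, _ in calls],
        "significant": [s for _, s, _ in calls],
        "direction": [d for _, _, d in calls],
        "score": 0.01,
    })


def flat_expr(genes, female=10.0, male=10.0):
    return pd.DataFrame({"female": female, "male": male},
                        index=pd.Index(genes, name="gene_id"))


class TestInternalDE:
    def test_extreme_separation_is_significant(self, small_study):
        cm, lengths = small_study["cm"], small_study["lengths"]
        calls = internal_de_test(cm, lengths)
        # the simulation plants sex-specific genes: zero in one sex, high in
        # the other; those with decent expression must be recovered
        truth = small_study["truth"].set_index("gene_id")
        strong = truth[(truth["sex_specific"] == "female_specific")
                       & (truth["baseline"] > truth["baseline"].median())]
        found = calls.set_index("gene").loc[strong.index]
        assert found["significant"].mean() > 0.8
        assert (found.loc[found["significant"], "direction"] == "female").all()

    def test_constant_counts_not_significant(self):
        genes = [f"g{i}" for i in range(50)]
        counts = pd.DataFrame(100, index=pd.Index(genes, name="gene_id"),
                              columns=[f"s{i}" for i in range(6)])
        samples = pd.DataFrame({
            "sex": ["female"] * 3 + ["male"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
            "species": "A",
        }, index=pd.Index(counts.columns, name="sample"))
        from dosagecomp import CountMatrix

        cm = CountMatrix(counts, samples)
        lengths = pd.Series(1000, index=pd.Index(genes))
        calls = internal_de_test(cm, lengths)
        assert not calls["significant"].any()

    def test_single_replicate_directs_to_external_calls(self):
        genes = ["g0", "g1"]
        counts = pd.DataFrame([[5, 9], [3, 2]],
                              index=pd.Index(genes, name="gene_id"),
                              columns=["f1", "m1"])
        samples = pd.DataFrame({"sex": ["female", "male"], "replicate": [1, 1],
                                "species": "A"},
                               index=pd.Index(["f1", "m1"], name="sample"))
        from dosagecomp import CountMatrix

        cm = CountMatrix(counts, samples)
        with pytest.raises(ValueError, match="external"):
            internal_de_test(cm, pd.Series(1000, index=pd.Index(genes)))


class TestConsensus:
    GENES = ["g0", "g1", "g2"]

    def _expr(self):
        return flat_expr(self.GENES, female=[20.0, 5.0, 10.0],
                         male=[5.0, 20.0, 10.0])

    def test_two_of_three_agreeing_is_biased(self):
        a = call_table("ma", [("g0", True, "female"), ("g1", False, "male"),
                              ("g2", False, "male")])
        b = call_table("mb", [("g0", True, "female"), ("g1", True, "male"),
                              ("g2", False, "male")])
        c = call_table("mc", [("g0", False, "male"), ("g1", False, "male"),
                              ("g2", False, "male")])
        calls = consensus_calls([a, b, c], self._expr())
        row = calls.set_index("gene").loc["g0"]
        assert row["consensus"] == "female_biased"
        assert row["n_supporting"] == 2
        assert calls.set_index("gene").loc["g1", "consensus"] == "unbiased"

    def test_single_method_support_is_unbiased(self):
        a = call_table("ma", [("g0", True, "male"), ("g1", False, "male"),
                              ("g2", False, "male")])
        b = call_table("mb", [("g0", False, "male"), ("g1", False, "male"),
                              ("g2", False, "male")])
        calls = consensus_calls([a, b], self._expr())
        assert (calls["consensus"] == "unbiased").all()

    def test_direction_conflict_is_unbiased(self):
        a = call_table("ma", [("g0", True, "male"), ("g1", False, "male"),
                              ("g2", False, "male")])
        b = call_table("mb", [("g0", True, "female"), ("g1", False, "male"),
                              ("g2", False, "male")])
        c = call_table("mc", [("g0", False, "male"), ("g1", False, "male"),
                              ("g2", False, "male")])
        calls = consensus_calls([a, b, c], self._expr())
        assert calls.set_index("gene").loc["g0", "consensus"] == "unbiased"

    def test_adding_agreeing_support_never_demotes(self):
        a = call_table("ma", [("g0", True, "female"), ("g1", True, "male"),
                              ("g2", False, "male")])
        b = call_table("mb", [("g0", True, "female"), ("g1", True, "male"),
                              ("g2", False, "male")])
        c = call_table("mc", [("g0", True, "female"), ("g1", True, "male"),
                              ("g2", True, "male")])
        before = consensus_calls([a, b], self._expr()).set_index("gene")
        after = consensus_calls([a, b, c], self._expr()).set_index("gene")
        for gene in self.GENES:
            if before.loc[gene, "consensus"] != "unbiased":
                assert after.loc[gene, "consensus"] == \
                    before.loc[gene, "consensus"]
                assert after.loc[gene, "n_supporting"] >= \
                    before.loc[gene, "n_supporting"]

    def test_fewer_than_two_methods_rejected(self):
        a = call_table("ma", [("g0", True, "male")])
        with pytest.raises(ValueError, match="2 distinct methods"):
            consensus_calls([a], flat_expr(["g0"]))

    def test_mismatched_universes_rejected(self):
        a = call_table("ma", [("g0", True, "male")])
        b = call_table("mb", [("g1", True, "male")])
        with pytest.raises(ValueError, match="universe"):
            consensus_calls([a, b], flat_expr(["g0", "g1"]))

    def test_sex_specific_labeling(self):
        a = call_table("ma", [("g0", True, "female"), ("g1", True, "male")])
        b = call_table("mb", [("g0", True, "female"), ("g1", True, "male")])
        expr = flat_expr(["g0", "g1"], female=[30.0, 0.0], male=[0.0, 30.0])
        calls = consensus_calls([a, b], expr).set_index("gene")
        assert calls.loc["g0", "specific"] == "female_specific"
        assert calls.loc["g1", "specific"] == "male_specific"
        # oriented ratio uses the pseudocount against the zero sex
        assert calls.loc["g0", "log2_ratio"] == \
            pytest.approx(np.log2(30.01 / 0.01))


class TestBinning:
    def _calls(self, log2_ratios, specific=None):
        genes = [f"g{i}" for i in range(len(log2_ratios))]
        return pd.DataFrame({
            "gene": genes,
            "consensus": "female_biased",
            "n_supporting": 2,
            "log2_ratio": log2_ratios,
            "specific": specific or ["none"] * len(genes),
        })

    def test_log2_of_4_2_lands_below_16(self):
        # 2^4.2 ~ 18.4 lands in the unbounded top bin over edges {2,4,8,16}
        calls = self._calls([4.2])
        arms = pd.Series(["X"], index=["g0"])
        out = bin_by_magnitude(calls, arms, bin_edges=(2, 4, 8, 16))
        hit = out[out["n_genes"] > 0]
        assert hit["bin"].tolist() == ["[16,inf)"]

    def test_exact_edge_goes_to_higher_bin(self):
        calls = self._calls([2.0])  # fold ratio exactly 4
        arms = pd.Series(["2R"], index=["g0"])
        out = bin_by_magnitude(calls, arms, bin_edges=(2, 4, 8, 16))
        hit = out[out["n_genes"] > 0]
        assert hit["bin"].tolist() == ["[4,8)"]

    def test_sex_specific_goes_to_top_bin(self):
        calls = self._calls([0.5], specific=["female_specific"])
        arms = pd.Series(["X"], index=["g0"])
        out = bin_by_magnitude(calls, arms, bin_edges=(2, 4, 8, 16))
        hit = out[out["n_genes"] > 0]
        assert hit["bin"].tolist() == ["[16,inf)"]

    def test_no_biased_genes_gives_all_zero(self):
        calls = self._calls([1.0])
        calls["consensus"] = "unbiased"
        arms = pd.Series(["X"], index=["g0"])
        out = bin_by_magnitude(calls, arms)
        assert out["n_genes"].sum() == 0

    def test_bins_partition_biased_genes(self, rng):
        ratios = rng.exponential(2.0, 200)
        calls = self._calls(ratios)
        arms = pd.Series(rng.choice(["X", "2R", "3L"], 200),
                         index=calls["gene"])
        out = bin_by_magnitude(calls, arms)
        per_arm = out.groupby("arm", observed=True)["n_genes"].sum()
        truth = arms.value_counts()
        assert per_arm.sort_index().tolist() == truth.sort_index().tolist()

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_by_magnitude(self._calls([1.0]),
                             pd.Series(["X"], index=["g0"]),
                             bin_edges=(4, 2))


class TestPermutation:
    def test_small_case_matches_exact_enumeration(self):
        # 10 genes, 2 on X, 3 biased all autosomal:
        # depletion p = C(8,3)/C(10,3) = 56/120
        arms = pd.Series(["X"] * 2 + ["2R"] * 8,
                         index=[f"g{i}" for i in range(10)])
        biased = [f"g{i}" for i in range(2, 5)]
        res = permutation_distribution_test(arms, biased, side="depletion",
                                            n_perm=10_000, seed=5)
        exact = 1 - float(hypergeom_upper_tail_exact(1, 10, 2, 3))
        assert exact == pytest.approx(56 / 120, abs=1e-15)
        assert res.p_hyper == pytest.approx(exact, abs=1e-12)
        assert abs(res.p_perm - exact) < 0.02

    def test_saturated_set_has_p_one_both_sides(self):
        arms = pd.Series(["X"] * 3 + ["2L"] * 7,
                         index=[f"g{i}" for i in range(10)])
        for side in ("depletion", "enrichment"):
            res = permutation_distribution_test(arms, arms.index, side=side,
                                                n_perm=1000, seed=1)
            assert res.p_perm == pytest.approx(1.0)
            assert res.observed_prop == pytest.approx(0.3)

    def test_permutation_converges_to_hypergeometric(self, rng):
        arms = pd.Series(np.where(rng.random(400) < 0.2, "X", "2R"),
                         index=[f"g{i}" for i in range(400)])
        biased = rng.choice(arms.index, 80, replace=False)
        n_perm = 20_000
        for side in ("depletion", "enrichment"):
            res = permutation_distribution_test(arms, biased, side=side,
                                                n_perm=n_perm, seed=11)
            se = np.sqrt(res.p_hyper * (1 - res.p_hyper) / n_perm)
            assert abs(res.p_perm - res.p_hyper) < 3 * se + 2 / n_perm

    def test_reproducible_given_seed(self):
        arms = pd.Series(["X"] * 30 + ["2R"] * 70,
                         index=[f"g{i}" for i in range(100)])
        biased = [f"g{i}" for i in range(0, 50, 2)]
        a = permutation_distribution_test(arms, biased, n_perm=500, seed=3)
        b = permutation_distribution_test(arms, biased, n_perm=500, seed=3)
        assert a == b

    def test_no_x_genes_rejected(self):
        arms = pd.Series(["2R"] * 10, index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="X chromosome"):
            permutation_distribution_test(arms, ["g1"])

    def test_stray_biased_gene_rejected(self):
        arms = pd.Series(["X", "2R"], index=["g0", "g1"])
        with pytest.raises(ValueError, match="missing"):
            permutation_distribution_test(arms, ["g7"])


class TestThresholdSweep:
    @staticmethod
    def _calls_with_planted_depletion():
        """Strongly male-biased genes (fold >= 8) never sit on the X, while
        the weakly biased set keeps the genome-wide X share of 20%."""
        n_weak, n_strong, n_unbiased = 450, 150, 600
        genes = [f"g{i}" for i in range(n_weak + n_strong + n_unbiased)]
        # weak biased: folds spread over [1.5, 4), 120/450 on X so the
        # threshold-1.5 biased set sits exactly at the null X share
        weak_arms = ["X"] * 120 + ["2R"] * (n_weak - 120)
        weak_log2r = np.linspace(np.log2(1.5), np.log2(3.99), n_weak)
        strong_arms = ["2R"] * n_strong
        unbiased_arms = ["X"] * 120 + ["2R"] * (n_unbiased - 120)
        arms = pd.Series(weak_arms + strong_arms + unbiased_arms, index=genes)
        calls = pd.DataFrame({
            "gene": genes,
            "consensus": ["male_biased"] * (n_weak + n_strong)
                         + ["unbiased"] * n_unbiased,
            "n_supporting": 2,
            "log2_ratio": np.concatenate([weak_log2r,
                                          np.full(n_strong, 3.0),
                                          np.full(n_unbiased, 0.1)]),
            "specific": "none",
        })
        return calls, arms

    def test_planted_demasculinization_found_above_threshold(self):
        calls, arms = self._calls_with_planted_depletion()
        sweep = threshold_sweep(calls, arms, [1.5, 4, 8], direction="male",
                                n_perm=2000, seed=9)
        dep = sweep[sweep["side"] == "depletion"].set_index("threshold")
        assert dep.loc[4.0, "p_perm"] < 0.05
        assert dep.loc[8.0, "p_perm"] < 0.05
        assert dep.loc[1.5, "p_perm"] > 0.05
        assert smallest_significant_threshold(sweep, "depletion") == 4.0

    def test_null_sweep_finds_nothing(self, rng):
        n = 1000
        genes = [f"g{i}" for i in range(n)]
        arms = pd.Series(np.where(rng.random(n) < 0.2, "X", "3R"), index=genes)
        calls = pd.DataFrame({
            "gene": genes,
            "consensus": np.where(rng.random(n) < 0.4, "female_biased",
                                  "unbiased"),
            "n_supporting": 2,
            "log2_ratio": rng.exponential(1.5, n),
            "specific": "none",
        })
        sweep = threshold_sweep(calls, arms, [1.5, 2, 4], direction="female",
                                n_perm=2000, seed=10)
        assert (sweep["p_perm"].dropna() > 0.01).all()

    def test_saturated_single_threshold(self):
        genes = [f"g{i}" for i in range(40)]
        arms = pd.Series(["X"] * 10 + ["2L"] * 30, index=genes)
        calls = pd.DataFrame({"gene": genes, "consensus": "male_biased",
                              "n_supporting": 2, "log2_ratio": 5.0,
                              "specific": "none"})
        sweep = threshold_sweep(calls, arms, [1.0], direction="male",
                                n_perm=500, seed=2)
        assert (sweep["p_perm"] == 1.0).all()

    def test_empty_thresholds_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep(pd.DataFrame(), pd.Series(dtype=object), [])


def test_sexbias_stage_is_reproducible(small_study):
    cm, lengths = small_study["cm"], small_study["lengths"]
    from dosagecomp import sex_expression

    expr = sex_expression(cm, lengths)
    arms = small_study["arms"]

    def run():
        methods = [internal_de_test(cm, lengths, method="welch_t"),
                   internal_de_test(cm, lengths, method="pooled_proportion")]
        calls = consensus_calls(methods, expr)
        sweep = threshold_sweep(calls, arms, [1.5, 2, 4], direction="male",
                                n_perm=500, seed=77)
        return calls.to_csv() + sweep.to_csv()

    assert run() == run()
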
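"""Group-level trait statistics: t-tests, FDR calling, PCA, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from phenomap import (
    PanelConfig,
    PlantedShift,
    atypicality_rank,
    basal_normalize,
    call_specific_traits,
    class_enrichment,
    group_difference_test,
    pca_anova,
    rate_efficiency_structure,
    simulate_panel,
    variance_profile,
)
from phenomap.containers import TraitMatrix
from phenomap.stats import bh_reject


def brute_force_bh(p, q):
    """Independent step-up oracle: search all m candidate cut-offs."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for i in range(1, m + 1):  # p_(i) <= i*q/m, take the largest such i
        if p[order[i - 1]] <= i * q / m:
            k_star = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestBenjaminiHochberg:
    def test_worked_step_up_case(self):
        # thresholds i*q/m: 0.0125, 0.025, 0.0375, 0.05 -> 3 rejections
        reject, _ = bh_reject([0.001, 0.01, 0.02, 0.9], q=0.05)
        assert int(reject.sum()) == 3

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            m = int(rng.integers(1, 51))
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            q = float(rng.uniform(0.005, 0.2))
            got, _ = bh_reject(p, q)
            assert np.array_equal(got, brute_force_bh(p, q))

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50),
        st.floats(0.005, 0.3),
    )
    @settings(max_examples=100, deadline=None)
    def test_bonferroni_calls_subset_of_bh_calls(self, p, q):
        p = np.asarray(p)
        bonf = p <= q / len(p)
        bh, _ = bh_reject(p, q)
        assert np.all(bh[bonf])


class TestGroupDifference:
    def test_null_groups_have_no_significant_traits(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.normal(size=(20, 100)),
            index=[f"s{i}" for i in range(20)],
            columns=[f"E{i:03d}|rate" for i in range(100)],
        )
        matrix = TraitMatrix(values)
        _, summary = group_difference_test(
            matrix, values.index[:10], values.index[10:], alpha=0.1
        )
        assert summary["fraction_significant"] <= 0.02

    def test_planted_shift_recovered(self):
        # 5-sd mean shift in 20 of 100 traits, 10 vs 10 strains
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 100))
        x[:10, :20] += 5.0
        values = pd.DataFrame(
            x, index=[f"s{i}" for i in range(20)],
            columns=[f"E{i:03d}|rate" for i in range(100)],
        )
        matrix = TraitMatrix(values)
        result, summary = group_difference_test(
            matrix, values.index[:10], values.index[10:], alpha=0.1
        )
        hits = result.iloc[:20]["significant"].sum()
        assert hits >= 19
        assert summary["n_superior_a"] >= 19

    def test_degenerate_all_equal_trait_gives_p_one(self):
        values = pd.DataFrame(
            {"E001|lag": [1.0, 1.0, 1.0, 1.0]}, index=list("abcd")
        )
        result, _ = group_difference_test(
            TraitMatrix(values), ["a", "b"], ["c", "d"]
        )
        assert result["p"].iloc[0] == pytest.approx(1.0)

    def test_sparse_traits_skipped_and_reported(self, tiny_matrix):
        result, summary = group_difference_test(
            tiny_matrix, ["s1", "s2"], ["s3", "s4"]
        )
        assert summary["n_skipped"] == 1  # E002|lag has one value in group b
        assert not result.loc[result["trait_id"] == "E002|lag", "tested"].iloc[0]


class TestSpecificTraits:
    def test_planted_population_shift_called_at_expected_fraction(self):
        # study-scale panel: 5 populations x 8 strains ~ the 39-isolate design
        cfg = PanelConfig(
            populations={f"P{i}": 8 for i in range(1, 6)},
            n_environments=200,
            shifts=(PlantedShift("P1", fraction_of_traits=0.35, effect_sd=2.0),),
            seed=7,
        )
        matrix, ann, _, truth = simulate_panel(cfg)
        calls, summary = call_specific_traits(matrix, ann.populations(), fdr=0.02)
        frac = summary["calls_per_group"]["P1"] / matrix.n_traits
        assert 0.30 <= frac <= 0.40
        called = set(
            calls.loc[(calls["group"] == "P1") & calls["significant"], "trait_id"]
        )
        true_traits = truth.shifted_traits("P1")
        # almost all calls are planted traits
        assert len(called & true_traits) / max(len(called), 1) > 0.95

    def test_null_panel_rarely_calls(self, null_panel):
        matrix, ann, _, _ = null_panel
        _, summary = call_specific_traits(matrix, ann.populations(), fdr=0.02)
        total = sum(summary["calls_per_group"].values())
        assert total / (matrix.n_traits * 5) <= 0.03

    def test_single_strain_group_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(
            rng.normal(size=(5, 30)),
            index=[f"s{i}" for i in range(5)],
            columns=[f"E{i:03d}|lag" for i in range(30)],
        )
        labels = pd.Series(["P1", "P1", "P2", "P2", "P3"], index=values.index)
        _, summary = call_specific_traits(TraitMatrix(values), labels, fdr=0.05)
        assert summary["excluded_small_groups"] == ["P3"]

    def test_sensitivity_curve_is_monotone_in_fdr(self, null_panel):
        matrix, ann, _, _ = null_panel
        _, summary = call_specific_traits(
            matrix, ann.populations(), fdr=0.02, fdr_grid=(0.005, 0.02, 0.05)
        )
        for counts in summary["sensitivity_curve"].values():
            assert counts[0.005] <= counts[0.02] <= counts[0.05]

    def test_invariant_to_strain_order_and_all_missing_traits(self, null_panel):
        matrix, ann, _, _ = null_panel
        calls_a, _ = call_specific_traits(matrix, ann.populations(), fdr=0.02)
        shuffled = matrix.subset_strains(list(matrix.strains)[::-1])
        values = shuffled.values.copy()
        values["E999|lag"] = np.nan
        padded = TraitMatrix(values)
        calls_b, _ = call_specific_traits(padded, ann.populations(), fdr=0.02)
        key = ["group", "trait_id"]
        a = calls_a.sort_values(key).reset_index(drop=True)
        b = calls_b.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestBasalNormalize:
    def test_basal_trait_becomes_zero_and_shared_defect_cancels(self):
        values = pd.DataFrame(
            {
                "BASAL|rate": [-2.0, 0.0],
                "STRESS|rate": [-2.0, 1.0],
            },
            index=["a", "b"],
        )
        normalized, report = basal_normalize(TraitMatrix(values), "BASAL")
        assert normalized.values.loc["a", "BASAL|rate"] == 0.0
        # strain a's defect is general, not stress-specific
        assert normalized.values.loc["a", "STRESS|rate"] == 0.0
        assert normalized.values.loc["b", "STRESS|rate"] == 1.0

    def test_missing_basal_environment_raises(self, tiny_matrix):
        with pytest.raises(ValueError, match="E999"):
            basal_normalize(tiny_matrix, "E999")


class TestVarianceProfile:
    def test_identical_values_have_zero_variance(self):
        values = pd.DataFrame(
            {"E001|lag": [1.0, 1.0, 2.0, 3.0]}, index=list("abcd")
        )
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        out = variance_profile(TraitMatrix(values), groups)
        assert out["mean_variance"]["g1"] == pytest.approx(0.0)

    def test_recovers_configured_variance_ratio(self):
        rng = np.random.default_rng(9)
        n, t = 40, 400
        a = rng.normal(0, np.sqrt(1.6), size=(n, t))
        b = rng.normal(0, 1.0, size=(n, t))
        values = pd.DataFrame(
            np.vstack([a, b]),
            index=[f"s{i}" for i in range(2 * n)],
            columns=[f"E{i:03d}|rate" for i in range(t)],
        )
        groups = pd.Series(["A"] * n + ["B"] * n, index=values.index)
        out = variance_profile(TraitMatrix(values), groups, pair=("A", "B"))
        assert out["variance_ratio"] == pytest.approx(1.6, rel=0.1)

    def test_leave_one_out_ratios_stay_close(self):
        rng = np.random.default_rng(10)
        values = pd.DataFrame(
            rng.normal(size=(30, 100)),
            index=[f"s{i}" for i in range(30)],
            columns=[f"E{i:03d}|lag" for i in range(100)],
        )
        groups = pd.Series(["A"] * 15 + ["B"] * 15, index=values.index)
        subpops = pd.Series(
            ["p1"] * 5 + ["p2"] * 5 + ["p3"] * 5, index=values.index[:15]
        )
        out = variance_profile(
            TraitMatrix(values), groups, pair=("A", "B"), leave_one_out=subpops
        )
        assert set(out["leave_one_out_ratios"]) == {"p1", "p2", "p3"}
        for ratio in out["leave_one_out_ratios"].values():
            assert 0.5 < ratio < 2.0


class TestPcaAnova:
    def test_pure_population_signal_loads_on_pc1(self):
        # variation only along population mean differences
        strains = [f"s{i}" for i in range(20)]
        pops = pd.Series(["P1"] * 10 + ["P2"] * 10, index=strains)
        srcs = pd.Series((["wild", "lab"] * 10)[:20], index=strains)
        base = np.where(np.arange(20) < 10, 1.0, -1.0)
        rng = np.random.default_rng(2)
        x = np.outer(base, rng.normal(size=50))
        values = pd.DataFrame(
            x, index=strains, columns=[f"E{i:03d}|rate" for i in range(50)]
        )
        out = pca_anova(TraitMatrix(values), pops, srcs, n_components=3)
        top = out["components"].iloc[0]
        assert top["variance_explained"] > 0.99
        assert top["population_r2"] > 0.99
        assert top["source_r2"] < 0.2

    def test_population_effect_dominates_source_effect(self):
        cfg = PanelConfig(
            n_environments=60,
            shifts=tuple(
                PlantedShift(f"P{i}", fraction_of_traits=0.3, effect_sd=3.0,
                             direction=(-1) ** i)
                for i in range(1, 6)
            ),
            seed=21,
        )
        matrix, ann, _, _ = simulate_panel(cfg)
        out = pca_anova(matrix, ann.populations(), ann.sources())
        top = out["components"].iloc[0]
        assert top["population_r2"] > top["source_r2"]
        assert out["n_complete_traits"] == matrix.n_traits

    def test_requesting_too_many_components_truncates(self, tiny_matrix):
        pops = pd.Series(["P1", "P1", "P2", "P2"], index=tiny_matrix.strains)
        out = pca_anova(tiny_matrix, pops, pops, n_components=10)
        assert out["truncated"]
        assert len(out["components"]) <= 3
        ve = out["components"]["variance_explained"]
        assert (ve >= 0).all() and ve.sum() <= 1.0 + 1e-9


class TestClassEnrichment:
    def test_proportional_calls_are_unenriched(self):
        traits = [f"t{i}" for i in range(40)]
        classes = pd.Series(["c1"] * 20 + ["c2"] * 20, index=traits)
        called = traits[:5] + traits[20:25]  # 25% of each class
        out = class_enrichment(called, traits, classes)
        assert (out["p"] > 0.5).all()

    def test_hand_computed_fisher_table(self):
        # 2x2 table [[1, 9], [11, 3]]: p from the exact hypergeometric sum
        traits = [f"t{i}" for i in range(24)]
        classes = pd.Series(["c1"] * 12 + ["c2"] * 12, index=traits)
        called = traits[:1] + traits[12:21]  # 1 of c1, 9 of c2 called
        out = class_enrichment(called, traits, classes).set_index(
            "environment_class"
        )
        # oracle: two-sided Fisher p by summing hypergeometric tail terms
        def hyp(a):
            return (
                comb(12, a) * comb(12, 10 - a) / comb(24, 10)
            )
        p0 = hyp(1)
        oracle = sum(hyp(a) for a in range(0, 11) if hyp(a) <= p0 + 1e-12)
        assert out.loc["c1", "p"] == pytest.approx(oracle, rel=1e-6)
        assert out.loc["c1", "p"] == pytest.approx(0.0028, abs=0.0005)
        assert out.loc["c1", "direction"] == "under"

    def test_empty_call_set_gives_p_one(self):
        traits = ["t1", "t2"]
        classes = pd.Series(["c1", "c2"], index=traits)
        out = class_enrichment([], traits, classes)
        assert (out["p"] == 1.0).all()


class TestAtypicality:
    def test_identical_strains_rank_stably_by_id(self):
        values = pd.DataFrame(
            np.tile(np.linspace(-1, 1, 20), (4, 1)) + 1e-9,
            index=["d", "c", "b", "a"],
            columns=[f"E{i:03d}|lag" for i in range(20)],
        )
        out = atypicality_rank(TraitMatrix(values))
        assert list(out["strain_id"]) == ["a", "b", "c", "d"]

    def test_resampled_outlier_is_most_atypical(self):
        rng = np.random.default_rng(4)
        shared = rng.normal(size=30)
        x = np.tile(shared, (6, 1)) + rng.normal(0, 0.1, size=(6, 30))
        x[0] = rng.normal(size=30)  # independently resampled profile
        values = pd.DataFrame(
            x, index=[f"s{i}" for i in range(6)],
            columns=[f"E{i:03d}|rate" for i in range(30)],
        )
        out = atypicality_rank(TraitMatrix(values))
        assert out.iloc[0]["strain_id"] == "s0"
        assert out.iloc[0]["rank"] == 1

    def test_excluded_strains_still_ranked_but_not_in_mean(self):
        rng = np.random.default_rng(8)
        shared = rng.normal(size=30)
        x = np.tile(shared, (5, 1)) + rng.normal(0, 0.05, size=(5, 30))
        x[4] = -shared  # an auxotroph with an inverted profile
        values = pd.DataFrame(
            x, index=[f"s{i}" for i in range(5)],
            columns=[f"E{i:03d}|rate" for i in range(30)],
        )
        out = atypicality_rank(TraitMatrix(values), exclude_from_mean=["s4"])
        assert out.iloc[0]["strain_id"] == "s4"
        assert out.iloc[0]["correlation"] < -0.9


class TestRateEfficiencyStructure:
    def test_exact_affine_relation_gives_r_one(self):
        rng = np.random.default_rng(6)
        strains = [f"s{i}" for i in range(20)]
        cols = {}
        for e in range(10):
            rate = rng.normal(size=20)
            cols[f"E{e:03d}|rate"] = rate
            cols[f"E{e:03d}|efficiency"] = 2.0 * rate + 0.3
            cols[f"E{e:03d}|lag"] = rng.normal(size=20)
        out = rate_efficiency_structure(
            TraitMatrix(pd.DataFrame(cols, index=strains))
        )
        assert out["overall_r"] == pytest.approx(1.0, abs=1e-9)
        assert out["fraction_env_r_above_cutoff"] == 1.0

    def test_independent_lag_is_uncorrelated(self):
        rng = np.random.default_rng(7)
        strains = [f"s{i}" for i in range(100)]
        cols = {}
        for e in range(20):  # 2000 (strain, environment) pairs
            cols[f"E{e:03d}|rate"] = rng.normal(size=100)
            cols[f"E{e:03d}|efficiency"] = rng.normal(size=100)
            cols[f"E{e:03d}|lag"] = rng.normal(size=100)
        out = rate_efficiency_structure(
            TraitMatrix(pd.DataFrame(cols, index=strains))
        )
        assert abs(out["lag_rate_r"]) < 0.1
        assert abs(out["lag_efficiency_r"]) < 0.1

    def test_coupled_panel_reproduces_configured_correlation(self):
        cfg = PanelConfig(n_environments=100, rate_efficiency_coupling=0.7,
                          noise_sd=0.05, seed=12)
        matrix, _, _, _ = simulate_panel(cfg)
        out = rate_efficiency_structure(matrix)
        assert out["overall_r"] == pytest.approx(0.7, abs=0.1)
        assert abs(out["lag_rate_r"]) < 0.15
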
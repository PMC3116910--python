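"""Genotype-phenotype association tests: CNV ratios, binary alleles, QTL filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenomap import (
    PanelConfig,
    PlantedCNV,
    PlantedStop,
    associate_features,
    bin_summary,
    binary_feature_assoc,
    cnv_assoc,
    cnv_ratio,
    qtl_crosscheck,
    simulate_panel,
)


class TestCnvRatio:
    @pytest.mark.parametrize("obs,exp,val", [
        (10, 10, 0.0),
        (0, 0, 0.0),
        (30, 10, np.log(31 / 11)),
    ])
    def test_identities(self, obs, exp, val):
        assert cnv_ratio(obs, exp) == pytest.approx(val, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            cnv_ratio(-1, 5)

    @given(st.integers(0, 10_000), st.integers(0, 10_000), st.integers(1, 100))
    @settings(max_examples=100, deadline=None)
    def test_strictly_monotone_in_both_arguments(self, obs, exp, delta):
        base = cnv_ratio(obs, exp)
        assert cnv_ratio(obs + delta, exp) > base
        assert cnv_ratio(obs, exp + delta) < base


class TestBinaryAssociation:
    def test_null_feature_rarely_candidate(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            g = pd.Series(np.r_[np.zeros(3), np.ones(18)],
                          index=[f"s{i}" for i in range(21)])
            y = pd.Series(rng.normal(size=21), index=g.index)
            res = binary_feature_assoc(g, y)
            hits += res["candidate"]
        assert hits <= 5

    def test_planted_large_effect_is_candidate(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(50):
            g = pd.Series(np.r_[np.zeros(3), np.ones(18)],
                          index=[f"s{i}" for i in range(21)])
            y = pd.Series(rng.normal(size=21), index=g.index)
            y.iloc[:3] -= 3.0  # carriers with a large lag defect
            hits += binary_feature_assoc(g, y)["candidate"]
        assert hits >= 40  # large majority of seeds

    def test_monomorphic_feature_untested(self):
        g = pd.Series(np.ones(10), index=[f"s{i}" for i in range(10)])
        y = pd.Series(np.random.default_rng(2).normal(size=10), index=g.index)
        assert binary_feature_assoc(g, y) is None

    def test_direction_reports_superior_class(self):
        g = pd.Series([0, 0, 0, 1, 1, 1], index=list("abcdef"), dtype=float)
        y = pd.Series([0, 0.1, -0.1, 5, 5.1, 4.9], index=list("abcdef"))
        res = binary_feature_assoc(g, y)
        assert res["direction"] == "class1_superior"


class TestCnvAssociation:
    def test_exact_linear_relation(self):
        x = pd.Series(np.linspace(0, 2, 12), index=[f"s{i}" for i in range(12)])
        res = cnv_assoc(x, 3.0 * x - 1.0)
        assert res["correlation"] == pytest.approx(1.0)
        assert res["candidate"]

    def test_recovers_generator_dose_slope(self):
        cfg = PanelConfig(populations={f"P{i}": 5 for i in range(1, 6)},
                          n_environments=10, cnv=PlantedCNV(), seed=3)
        matrix, _, fs, truth = simulate_panel(cfg)
        planted = truth.planted_features.iloc[0]
        ratios = fs.values[planted["feature_id"]]
        trait = matrix.values[planted["trait_id"]]
        res = cnv_assoc(ratios, trait)
        assert res["correlation"] > 0.6  # positive dose dependence
        slope = np.polyfit(ratios, trait, 1)[0]
        assert slope == pytest.approx(planted["effect"], rel=0.35)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(300):
            x = pd.Series(rng.normal(size=20), index=range(20))
            y = pd.Series(rng.normal(size=20), index=range(20))
            ps.append(cnv_assoc(x, y)["p"])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_ratio_untested(self):
        x = pd.Series(np.ones(10), index=range(10))
        y = pd.Series(np.random.default_rng(5).normal(size=10), index=range(10))
        assert cnv_assoc(x, y) is None


class TestBinSummary:
    def test_constant_trait_gives_equal_bin_means(self):
        x = pd.Series(np.arange(12, dtype=float))
        out = bin_summary(x, pd.Series(np.ones(12)), n_bins=4)
        assert np.allclose(out["mean_trait"], 1.0)

    def test_monotone_trait_gives_monotone_bin_means(self):
        x = pd.Series(np.arange(20, dtype=float))
        out = bin_summary(x, 2 * x, n_bins=5)
        assert out["mean_trait"].is_monotonic_increasing

    def test_too_many_bins_rejected(self):
        x = pd.Series(np.arange(4, dtype=float))
        with pytest.raises(ValueError, match="exceeds"):
            bin_summary(x, x, n_bins=10)

    def test_dose_effect_bins_rise(self):
        cfg = PanelConfig(populations={f"P{i}": 6 for i in range(1, 5)},
                          n_environments=5, cnv=PlantedCNV(), seed=6)
        matrix, _, fs, truth = simulate_panel(cfg)
        planted = truth.planted_features.iloc[0]
        out = bin_summary(fs.values[planted["feature_id"]],
                          matrix.values[planted["trait_id"]], n_bins=4)
        assert out["mean_trait"].iloc[-1] > out["mean_trait"].iloc[0]


class TestQtlCrosscheck:
    def _regions(self):
        return pd.DataFrame(
            {
                "cross_id": ["c1", "c2"],
                "chrom": ["chr04", "chr08"],
                "start": [400_000, 100_000],
                "end": [500_000, 300_000],
                "peak_marker": ["m1", "m2"],
                "lod": [12.0, 8.0],
            }
        )

    def test_locus_inside_an_interval_is_retained(self):
        cand = pd.DataFrame({"chrom": ["chr04"], "pos": [463_000]})
        out = qtl_crosscheck(cand, self._regions())
        assert out["retained"].iloc[0]

    def test_interval_bounds_are_inclusive(self):
        cand = pd.DataFrame({"chrom": ["chr04", "chr04", "chr04"],
                             "pos": [400_000, 500_000, 500_001]})
        out = qtl_crosscheck(cand, self._regions())
        assert list(out["retained"]) == [True, True, False]

    def test_chromosome_without_qtl_not_retained_with_warning(self):
        cand = pd.DataFrame({"chrom": ["chr13"], "pos": [50_000]})
        out = qtl_crosscheck(cand, self._regions())
        assert not out["retained"].iloc[0]
        assert out["warning"].iloc[0] == "chromosome_without_qtl"

    def test_candidacy_and_support_both_required(self):
        cand = pd.DataFrame(
            {"chrom": ["chr04", "chr04"], "pos": [463_000, 463_000],
             "candidate": [True, False]}
        )
        out = qtl_crosscheck(cand, self._regions())
        assert list(out["retained"]) == [True, False]


class TestAssociateFeatures:
    def _panel(self, seed=0, extra_mono=False):
        cfg = PanelConfig(
            populations={"P1": 3, "P2": 5, "P3": 5, "P4": 4, "P5": 4},
            n_environments=10,
            stop=PlantedStop(n_carriers=3, effect_sd=-3.0),
            cnv=PlantedCNV(),
            n_decoy_stops=1,
            n_decoy_cnvs=1,
            seed=seed,
        )
        return simulate_panel(cfg)

    def test_planted_stop_is_candidate(self):
        matrix, _, fs, truth = self._panel(seed=8)
        planted = truth.planted_features.set_index("feature_id")
        out = associate_features(fs, matrix, planted.loc["STOP_GENE", "trait_id"])
        row = out.set_index("feature_id").loc["STOP_GENE"]
        assert row["candidate"]

    def test_bonferroni_families_split_by_test_kind(self):
        matrix, _, fs, truth = self._panel(seed=9)
        out = associate_features(fs, matrix, matrix.trait_ids[0])
        fam = out.set_index("feature_id")["bonferroni_m"]
        assert fam["STOP_GENE"] == 2  # stop + decoy stop
        assert fam["CNV_GENE"] == 2  # cnv + decoy cnv

    def test_invariant_to_strain_order_and_monomorphic_features(self):
        matrix, _, fs, truth = self._panel(seed=10)
        tid = truth.planted_features["trait_id"].iloc[0]
        base = associate_features(fs, matrix, tid)
        # reverse strain order and append a monomorphic feature
        rev = matrix.subset_strains(list(matrix.strains)[::-1])
        feats = fs.features.copy()
        feats.loc["MONO"] = {"gene": "MONO", "chrom": "chr15", "pos": 1000,
                             "kind": "stop"}
        vals = fs.values.copy()
        vals["MONO"] = 1.0
        from phenomap.containers import GenotypeFeatureSet

        fs2 = GenotypeFeatureSet(feats, vals.loc[list(rev.strains)])
        out = associate_features(fs2, rev, tid)
        merged = base.merge(out, on="feature_id", suffixes=("_a", "_b"))
        assert np.allclose(merged["p_corrected_a"], merged["p_corrected_b"],
                           equal_nan=True)
        assert (merged["candidate_a"] == merged["candidate_b"]).all()
        mono = out.set_index("feature_id").loc["MONO"]
        assert not mono["tested"] and not mono["candidate"]
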
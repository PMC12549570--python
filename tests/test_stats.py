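import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rfpep.simulate import CohortDesign, simulate_experiment
from rfpep.stats import (differential_analysis, dunn_posthoc, fold_change,
                         holm_sidak, kruskal_wallis, normalize, volcano_table,
                         z_score)
from rfpep.tables import abundance_matrix

from .oracles import dunn_z_oracle, holm_sidak_oracle, kruskal_wallis_oracle


class TestNormalize:
    def make_matrix(self, rng, n_features=80, n_samples=6):
        base = rng.lognormal(mean=14, sigma=1.0, size=(n_features, 1))
        noise = rng.lognormal(mean=0, sigma=0.05, size=(n_features, n_samples))
        return pd.DataFrame(base * noise,
                            index=[f"F{i}" for i in range(n_features)],
                            columns=[f"S{j}" for j in range(n_samples)])

    def test_exact_scaling_recovered(self):
        rng = np.random.default_rng(0)
        mat = self.make_matrix(rng, n_samples=3)
        mat["S2"] = mat["S0"] * 2.0  # duplicate of S0 at double scale
        norm, factors = normalize(mat)
        ref = factors.idxmin() if factors.min() < 1 else factors.index[0]
        assert factors["S2"] == pytest.approx(2.0 * factors["S0"], rel=1e-9)
        pd.testing.assert_series_equal(norm["S2"], norm["S0"],
                                       check_names=False)

    def test_reference_sample_factor_is_one(self):
        rng = np.random.default_rng(1)
        mat = self.make_matrix(rng, n_samples=5)
        totals = mat.sum(axis=0)
        ref = (totals - totals.median()).abs().idxmin()
        _, factors = normalize(mat)
        assert factors[ref] == pytest.approx(1.0)

    def test_mad_filter_shrugs_off_contamination(self):
        rng = np.random.default_rng(2)
        mat = self.make_matrix(rng, n_features=200, n_samples=6)
        _, clean_factors = normalize(mat)
        dirty = mat.copy()
        spiked = rng.choice(200, size=10, replace=False)  # 5% of features
        dirty.iloc[spiked, 3] *= 100.0
        _, dirty_factors = normalize(dirty)
        assert dirty_factors.iloc[3] == pytest.approx(clean_factors.iloc[3],
                                                      rel=0.02)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            normalize(pd.DataFrame({"S1": [1.0, 2.0]}))


class TestZScore:
    def test_hand_example(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["F1"],
                           columns=["a", "b", "c"])
        out = z_score(mat)
        assert out.loc["F1"].tolist() == [-1.0, 0.0, 1.0]

    def test_constant_feature_becomes_zero(self):
        out = z_score(pd.DataFrame([[5.0, 5.0, 5.0]], index=["F1"]))
        assert (out.loc["F1"] == 0).all()

    def test_too_few_values_stay_missing(self):
        out = z_score(pd.DataFrame([[7.0, np.nan, np.nan]], index=["F1"]))
        assert out.loc["F1"].isna().all()

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(size=(5, 10)))
        out = z_score(mat)
        assert np.allclose(out.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)


class TestKruskalWallis:
    def test_worked_three_group_example(self):
        groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]),
                  np.array([7.0, 8, 9])]
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(7.2, abs=1e-12)
        assert h == pytest.approx(kruskal_wallis_oracle(groups), abs=1e-12)

    def test_identical_groups_are_null(self):
        h, p = kruskal_wallis([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p > 0.9

    def test_all_tied_values(self):
        h, p = kruskal_wallis([np.array([2.0, 2.0]), np.array([2.0, 2.0])])
        assert (h, p) == (0.0, 1.0)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(4)
        n_sim, alpha = 400, 0.05
        rejections = sum(
            kruskal_wallis([rng.normal(size=8) for _ in range(3)])[1] < alpha
            for _ in range(n_sim))
        rate = rejections / n_sim
        se = np.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(rate - alpha) < 2 * se + 0.01


class TestDunn:
    def test_worked_example_z(self):
        groups = {"g1": np.array([1.0, 2, 3]), "g2": np.array([4.0, 5, 6]),
                  "g3": np.array([7.0, 8, 9])}
        out = dunn_posthoc(groups)
        pair = out[(out.group_a == "g1") & (out.group_b == "g3")].iloc[0]
        assert abs(pair.z) == pytest.approx(6 / np.sqrt(5), abs=1e-12)
        oracle = dunn_z_oracle([groups["g1"], groups["g2"], groups["g3"]], 0, 2)
        assert pair.z == pytest.approx(oracle, abs=1e-12)

    def test_identical_groups_z_zero(self):
        out = dunn_posthoc({"a": np.array([1.0, 2, 3]),
                            "b": np.array([1.0, 2, 3])})
        assert out.iloc[0].z == pytest.approx(0.0, abs=1e-12)
        assert out.iloc[0].p == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        g = {"a": rng.normal(size=6), "b": rng.normal(size=9),
             "c": rng.normal(size=4)}
        out = dunn_posthoc(g)
        swapped = dunn_posthoc({"c": g["c"], "b": g["b"], "a": g["a"]})
        for _, row in out.iterrows():
            mirror = swapped[(swapped.group_a == row.group_b)
                             & (swapped.group_b == row.group_a)]
            if len(mirror):
                assert mirror.iloc[0].z == pytest.approx(-row.z, abs=1e-12)


class TestHolmSidak:
    def test_worked_example(self):
        adj = holm_sidak([0.01, 0.02, 0.04])
        assert adj == pytest.approx([0.029701, 0.039600, 0.04], abs=1e-9)
        assert adj == pytest.approx(holm_sidak_oracle([0.01, 0.02, 0.04]),
                                    abs=1e-12)

    def test_single_p_unchanged(self):
        assert holm_sidak([0.3])[0] == pytest.approx(0.3)

    def test_boundary_values(self):
        assert holm_sidak([0.0, 0.0]).tolist() == [0.0, 0.0]
        assert holm_sidak([1.0, 1.0]).tolist() == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=12))
    def test_matches_closed_form_oracle(self, ps):
        assert holm_sidak(ps) == pytest.approx(holm_sidak_oracle(ps),
                                               abs=1e-12)


class TestFoldChange:
    def test_simple_ratio(self):
        fc, flagged = fold_change(np.array([10.0, 10.0]), np.array([2.0, 2.0]),
                                  epsilon=0.1)
        assert fc == 5.0 and not flagged

    def test_zero_denominator_uses_epsilon(self):
        fc, flagged = fold_change(np.array([1.0]), np.array([0.0]),
                                  epsilon=0.1)
        assert fc == pytest.approx(10.0) and flagged

    def test_both_zero_is_unit_and_flagged(self):
        fc, flagged = fold_change(np.array([0.0]), np.array([0.0]),
                                  epsilon=0.1)
        assert fc == 1.0 and flagged

    def test_reciprocal_property(self):
        rng = np.random.default_rng(6)
        a, b = rng.lognormal(size=5), rng.lognormal(size=5)
        fab, _ = fold_change(a, b, 1e-9)
        fba, _ = fold_change(b, a, 1e-9)
        assert fab * fba == pytest.approx(1.0, rel=1e-12)


class TestVolcano:
    def test_threshold_points(self):
        diff = pd.DataFrame({"fc": [5.0, 1.0], "adj_p": [0.05, 1.0],
                             "call": ["ns", "ns"]},
                            index=["F1", "F2"])
        v = volcano_table(diff)
        assert v.loc["F1", "log2_fc"] == pytest.approx(np.log2(5))
        assert v.loc["F1", "neg_log10_adj_p"] == pytest.approx(-np.log10(0.05))
        assert v.loc["F2", "log2_fc"] == 0.0
        assert v.loc["F2", "neg_log10_adj_p"] == 0.0

    def test_zero_p_is_capped_and_flagged(self):
        diff = pd.DataFrame({"fc": [2.0], "adj_p": [0.0], "call": ["up"]},
                            index=["F1"])
        v = volcano_table(diff)
        assert np.isfinite(v.loc["F1", "neg_log10_adj_p"])
        assert bool(v.loc["F1", "p_capped"])


class TestDifferentialCalling:
    def test_null_cohort_controls_false_calls(self):
        design = CohortDesign(
            group_sizes={"RFposCCPpos_RA": 10, "RFnegCCPpos_RA": 4,
                         "RFnegCCPneg_RA": 8, "RFneg_control": 10,
                         "RFpos_control": 4},
            n_background_peptides=60, n_ig_peptides=30, n_upregulated=0,
            n_also_rfneg=0, n_discriminative=0, n_cdr_variants=0,
            isotype_effect_groups=(), effect_groups=(), seed=11)
        sim = simulate_experiment(design)
        norm, _ = normalize(abundance_matrix(sim.features))
        diff = differential_analysis(
            norm, {s.sample_id: s.group for s in sim.samples})
        assert (diff["call"] != "ns").mean() <= 0.05

    def test_planted_effects_are_called_up(self, sim_default):
        norm, _ = normalize(abundance_matrix(sim_default.features))
        diff = differential_analysis(
            norm, {s.sample_id: s.group for s in sim_default.samples})
        truth = sim_default.truth.set_index("feature_id")
        planted = truth.index[truth.upregulated | truth.discriminative]
        assert (diff.loc[planted, "call"] == "up").mean() >= 0.9
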
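import numpy as np
import pandas as pd
import pytest

from rfpep.splsda import (balanced_error_rate, cross_validate, mean_impute,
                          pca, select_discriminative, splsda_fit,
                          splsda_predict, splsda_tune)


def separable_data(seed=0, n_per_group=20, n_informative=3, n_noise=47,
                   shift=2.5):
    rng = np.random.default_rng(seed)
    p = n_informative + n_noise
    X = rng.normal(size=(2 * n_per_group, p))
    X[:n_per_group, :n_informative] += shift
    y = np.array(["case"] * n_per_group + ["control"] * n_per_group)
    return X, y


class TestPca:
    def test_collinear_data_has_single_component(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([t, 2 * t, -t])
        scores, loadings, evr = pca(X)
        assert evr[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 5))
        scores, loadings, evr = pca(X)
        recon = scores @ loadings.T + X.mean(axis=0)
        assert np.allclose(recon, X, atol=1e-10)
        assert evr.sum() == pytest.approx(1.0)

    def test_separated_groups_split_on_pc1(self):
        X, y = separable_data(seed=1)
        scores, _, _ = pca(X)
        a = scores[y == "case", 0]
        b = scores[y == "control", 0]
        gap = abs(a.mean() - b.mean())
        assert gap > 2 * max(a.std(), b.std())

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca(np.zeros((4, 4)))


class TestFit:
    def test_sparsity_off_limit_equals_dense_pls(self):
        X, y = separable_data(seed=2)
        model = splsda_fit(X, y, keepx=[X.shape[1]])
        # dense PLS-DA direction = dominant left singular vector of X'Y
        Xc = (X - X.mean(0)) / X.std(0, ddof=1)
        Y = np.column_stack([(y == c).astype(float) for c in sorted(set(y))])
        Yc = Y - Y.mean(0)
        u = np.linalg.svd(Xc.T @ Yc)[0][:, 0]
        w = model.weights[:, 0]
        cos = abs(u @ w) / (np.linalg.norm(u) * np.linalg.norm(w))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_keepx_controls_nonzero_loadings(self):
        X, y = separable_data(seed=3)
        model = splsda_fit(X, y, keepx=[3, 7])
        assert len(model.selected(0)) == 3
        assert len(model.selected(1)) == 7

    def test_informative_variables_selected(self):
        X, y = separable_data(seed=4)
        model = splsda_fit(X, y, keepx=[3])
        assert set(model.selected(0)) == {0, 1, 2}

    def test_duplicating_samples_keeps_direction(self):
        X, y = separable_data(seed=5)
        m1 = splsda_fit(X, y, keepx=[5])
        m2 = splsda_fit(np.vstack([X, X]), np.concatenate([y, y]), keepx=[5])
        assert np.allclose(m1.weights[:, 0], m2.weights[:, 0], atol=1e-8)

    def test_keepx_larger_than_p_rejected(self):
        X, y = separable_data(seed=6)
        with pytest.raises(ValueError):
            splsda_fit(X, y, keepx=[X.shape[1] + 1])


class TestPredict:
    def test_training_ber_zero_on_separable_data(self):
        X, y = separable_data(seed=7, shift=5.0)
        model = splsda_fit(X, y, keepx=[3, 3])
        assert balanced_error_rate(y, splsda_predict(model, X)) == 0.0

    def test_prediction_invariant_to_feature_order(self):
        X, y = separable_data(seed=8)
        perm = np.random.default_rng(0).permutation(X.shape[1])
        m1 = splsda_fit(X, y, keepx=[3, 3])
        m2 = splsda_fit(X[:, perm], y, keepx=[3, 3])
        assert (splsda_predict(m1, X) == splsda_predict(m2, X[:, perm])).all()

    def test_single_class_is_trivial(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 5))
        model = splsda_fit(X, ["only"] * 10, keepx=[2])
        assert (splsda_predict(model, X) == "only").all()


class TestCrossValidation:
    def test_deterministic_under_seed(self):
        X, y = separable_data(seed=10)
        cv1 = cross_validate(X, y, [3, 3], repeats=5, seed=42)
        cv2 = cross_validate(X, y, [3, 3], repeats=5, seed=42)
        assert np.array_equal(cv1.ber_per_repeat, cv2.ber_per_repeat)
        pd.testing.assert_series_equal(cv1.occurrence, cv2.occurrence)

    def test_informative_peptides_reach_full_occurrence(self):
        X, y = separable_data(seed=11)
        cv = cross_validate(X, y, [3], repeats=10, seed=1)
        assert (cv.occurrence.iloc[:3] > 0.5).all()
        assert cv.mean_ber <= 0.1

    def test_occurrence_denominator_models(self):
        X, y = separable_data(seed=12)
        cv = cross_validate(X, y, [3], repeats=5, seed=1,
                            occurrence_denominator="models")
        assert cv.occurrence.max() <= 1.0
        assert (cv.occurrence.iloc[:3] == 1.0).all()

    def test_pure_noise_ber_near_chance(self):
        rng = np.random.default_rng(13)
        bers = []
        for ds in range(6):
            X = rng.normal(size=(30, 20))
            y = np.array(["a", "b"] * 15)
            cv = cross_validate(X, y, [5], repeats=5, seed=ds)
            bers.append(cv.mean_ber)
        assert abs(np.mean(bers) - 0.5) < 0.12


class TestTune:
    def test_separable_data_tunes_to_small_keepx(self):
        X, y = separable_data(seed=14)
        tuned = splsda_tune(X, y, h_grid=(2, 3), keepx_grid=(1, 3, 10, 50),
                            repeats=5, seed=0)
        assert tuned.n_components == 2  # parsimony at equal (near-zero) BER
        assert tuned.keepx[0] <= 3
        assert min(tuned.ber_by_depth.values()) <= 0.1

    def test_same_seed_same_choice(self):
        X, y = separable_data(seed=15)
        t1 = splsda_tune(X, y, h_grid=(2,), keepx_grid=(1, 3, 10), repeats=3,
                         seed=5)
        t2 = splsda_tune(X, y, h_grid=(2,), keepx_grid=(1, 3, 10), repeats=3,
                         seed=5)
        assert (t1.n_components, t1.keepx) == (t2.n_components, t2.keepx)


class TestMeanImpute:
    def test_fills_missing_with_feature_mean(self):
        mat = pd.DataFrame([[1.0, np.nan, 3.0]], index=["F1"],
                           columns=list("abc"))
        out = mean_impute(mat)
        assert out.loc["F1", "b"] == pytest.approx(2.0)


class TestSelectDiscriminative:
    @staticmethod
    def frames():
        samples = [f"S{i}" for i in range(6)]
        groups = dict(zip(samples, ["RFposCCPpos_RA"] * 3
                          + ["RFneg_control"] * 3))
        z = pd.DataFrame(
            [[1, 1, 1, -1, -1, -1],    # control lowest
             [1, 1, 1, -1, -1, -1],
             [-1, -1, -1, 1, 1, 1]],   # control highest
            index=["P1", "P2", "P3"], columns=samples, dtype=float)
        diff = pd.DataFrame({"adj_p": [0.01, 0.01, 0.01],
                             "fc": [10.0, 10.0, 10.0]},
                            index=["P1", "P2", "P3"])
        return groups, z, diff

    def test_conjunction_of_all_criteria(self):
        groups, z, diff = self.frames()
        occurrence = pd.Series({"P1": 0.9, "P2": 0.4, "P3": 0.9})
        cats = {"P1": "variable", "P2": "variable", "P3": "variable"}
        out = select_discriminative(occurrence, diff, z, groups, cats)
        assert bool(out.loc["P1", "discriminative"])
        assert not out.loc["P2", "discriminative"]  # occurrence 0.4
        assert not out.loc["P3", "discriminative"]  # control not lowest

    def test_no_v_region_means_empty_selection(self):
        groups, z, diff = self.frames()
        occurrence = pd.Series(1.0, index=diff.index)
        cats = {"P1": "constant", "P2": "non_ig", "P3": "constant"}
        out = select_discriminative(occurrence, diff, z, groups, cats)
        assert not out["discriminative"].any()
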
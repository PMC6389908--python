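import numpy as np
import pandas as pd
import pytest

from _oracles import eig2x2, irls_logistic
from mirisk import spca_model as spca


def _frame(rng, n=50, p=4, prefix="M"):
    return pd.DataFrame(
        rng.normal(0, 1, (n, p)), columns=[f"{prefix}{j}" for j in range(p)]
    )


class TestFitPCA:
    def test_single_feature_component_is_unit_loading(self, rng):
        expr = _frame(rng, p=1)
        pca = spca.fit_pca(expr)
        assert pca.loadings.shape == (1, 1)
        assert pca.loadings[0, 0] == pytest.approx(1.0)
        scores = spca.project(pca, expr)
        np.testing.assert_allclose(
            scores[:, 0], expr.iloc[:, 0] - expr.iloc[:, 0].mean(), atol=1e-12
        )

    def test_two_feature_loadings_match_closed_form_eigenvectors(self, rng):
        expr = _frame(rng, n=200, p=2)
        expr.iloc[:, 1] = 0.6 * expr.iloc[:, 0] + 0.8 * expr.iloc[:, 1]
        pca = spca.fit_pca(expr)
        cov = np.cov(expr.to_numpy(), rowvar=False)
        eigvals, eigvecs = eig2x2(cov)
        np.testing.assert_allclose(pca.explained_variance, eigvals, atol=1e-8)
        for c in range(2):
            dot = abs(float(pca.loadings[:, c] @ eigvecs[:, c]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_loadings_orthonormal(self, rng):
        expr = _frame(rng, n=40, p=8)
        pca = spca.fit_pca(expr)
        gram = pca.loadings.T @ pca.loadings
        np.testing.assert_allclose(gram, np.eye(pca.n_components), atol=1e-10)

    def test_components_capped_at_n_samples_minus_one(self, rng):
        expr = _frame(rng, n=5, p=20)
        assert spca.fit_pca(expr).n_components == 4

    def test_sign_convention_largest_entry_positive(self, rng):
        expr = _frame(rng, n=60, p=6)
        pca = spca.fit_pca(expr)
        for c in range(pca.n_components):
            col = pca.loadings[:, c]
            assert col[np.abs(col).argmax()] > 0

    def test_zero_variance_submatrix_raises(self):
        expr = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="zero variance"):
            spca.fit_pca(expr)


class TestProject:
    def test_training_mean_vector_maps_to_origin(self, rng):
        expr = _frame(rng)
        pca = spca.fit_pca(expr)
        mean_row = pd.DataFrame([expr.mean()], columns=expr.columns)
        np.testing.assert_allclose(spca.project(pca, mean_row), 0.0, atol=1e-10)

    def test_hand_computed_two_feature_example(self):
        pca = spca.PCAModel(
            mirna_ids=["a", "b"],
            center=np.array([1.0, 2.0]),
            loadings=np.array([[0.6, 0.8], [0.8, -0.6]]),
            explained_variance=np.array([2.0, 1.0]),
        )
        sample = pd.DataFrame({"a": [2.0], "b": [4.0]})
        # centered = (1, 2); scores = (0.6+1.6, 0.8-1.2) = (2.2, -0.4)
        np.testing.assert_allclose(
            spca.project(pca, sample), [[2.2, -0.4]], atol=1e-12
        )

    def test_missing_feature_error_names_it(self, rng):
        expr = _frame(rng)
        pca = spca.fit_pca(expr)
        with pytest.raises(ValueError, match="M3"):
            spca.project(pca, expr.drop(columns="M3"))


class TestPCLogistic:
    def test_null_scores_give_near_zero_betas(self, rng):
        scores = rng.normal(0, 1, (500, 3))
        labels = rng.integers(0, 2, 500)
        betas, converged = spca.fit_pc_logistic(scores, labels, m=3)
        assert converged
        # SE of a null logistic coefficient on unit scores is ~2/sqrt(n)
        assert np.all(np.abs(betas) < 4 * 2 / np.sqrt(500))

    def test_known_coefficient_matches_irls_oracle(self, rng):
        scores = rng.normal(0, 1, (400, 1))
        p = 1 / (1 + np.exp(-1.5 * scores[:, 0]))
        labels = (rng.random(400) < p).astype(int)
        betas, converged = spca.fit_pc_logistic(scores, labels, m=1)
        beta_o, _ = irls_logistic(scores, labels)
        assert converged
        assert betas[0] == pytest.approx(beta_o[0], abs=1e-6)

    def test_m_exceeding_components_raises(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            spca.fit_pc_logistic(rng.normal(0, 1, (30, 2)), rng.integers(0, 2, 30), m=5)

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            spca.fit_pc_logistic(rng.normal(0, 1, (30, 2)), np.ones(30), m=1)


def _toy_model(betas, pi_cutoff=None):
    pca = spca.PCAModel(
        mirna_ids=["a", "b"],
        center=np.zeros(2),
        loadings=np.eye(2),
        explained_variance=np.array([1.0, 1.0]),
    )
    return spca.RiskModel(
        disease="AD", T=2.0, m=len(betas), pca=pca,
        betas=np.asarray(betas, float), pi_cutoff=pi_cutoff,
    )


class TestPrognosticIndex:
    def test_zero_betas_give_zero_pi(self, rng):
        model = _toy_model([0.0, 0.0])
        expr = pd.DataFrame(rng.normal(0, 1, (5, 2)), columns=["a", "b"])
        np.testing.assert_allclose(spca.prognostic_index(model, expr), 0.0)

    def test_toy_arithmetic(self):
        # beta=(2,-1), scores=(0.5,1.0) -> PI = 2*0.5 - 1*1.0 = 0
        model = _toy_model([2.0, -1.0])
        expr = pd.DataFrame({"a": [0.5], "b": [1.0]})
        assert spca.prognostic_index(model, expr).iloc[0] == pytest.approx(0.0)

    def test_classification_is_strict_inequality(self):
        model = _toy_model([1.0, 0.0], pi_cutoff=0.5)
        expr = pd.DataFrame({"a": [0.5, 0.5001], "b": [0.0, 0.0]})
        assert list(spca.classify(model, expr)) == [0, 1]

    def test_classification_without_cutoff_raises(self):
        model = _toy_model([1.0, 0.0])
        with pytest.raises(ValueError, match="cutoff"):
            spca.classify(model, pd.DataFrame({"a": [1.0], "b": [0.0]}))

    def test_pi_unchanged_by_non_selected_mirna(self, rng):
        model = _toy_model([2.0, -1.0])
        expr = pd.DataFrame(rng.normal(0, 1, (10, 3)), columns=["a", "b", "other"])
        pi1 = spca.prognostic_index(model, expr)
        pi2 = spca.prognostic_index(model, expr.assign(other=expr["other"] + 100.0))
        pd.testing.assert_series_equal(pi1, pi2)

    def test_pi_invariant_to_loading_sign_flip_after_refit(self, rng):
        expr = _frame(rng, n=300, p=5)
        labels = (rng.random(300) < 1 / (1 + np.exp(-expr["M0"]))).astype(int)
        pca = spca.fit_pca(expr)
        scores = spca.project(pca, expr)
        betas, _ = spca.fit_pc_logistic(scores, labels, m=3)
        pi = scores[:, :3] @ betas
        flipped = scores.copy()
        flipped[:, 1] *= -1
        betas_f, _ = spca.fit_pc_logistic(flipped, labels, m=3)
        np.testing.assert_allclose(flipped[:, :3] @ betas_f, pi, atol=1e-8)


class TestSerialization:
    def test_round_trip_preserves_model(self, tmp_path, rng):
        expr = _frame(rng, n=80, p=6)
        pca = spca.fit_pca(expr)
        betas, _ = spca.fit_pc_logistic(
            spca.project(pca, expr), rng.integers(0, 2, 80), m=2
        )
        model = spca.RiskModel(
            disease="VaD", T=1.5, m=2, pca=pca, betas=betas, pi_cutoff=0.3,
            provenance={"seed": 1},
        )
        path = tmp_path / "model.json"
        model.save(path)
        loaded = spca.RiskModel.load(path)
        np.testing.assert_array_equal(loaded.pca.loadings, model.pca.loadings)
        np.testing.assert_array_equal(loaded.betas, model.betas)
        assert loaded.pi_cutoff == model.pi_cutoff
        assert loaded.disease == "VaD"
        # byte-identical re-serialization
        loaded.save(tmp_path / "model2.json")
        assert (tmp_path / "model2.json").read_bytes() == path.read_bytes()

    def test_betas_length_must_match_m(self, rng):
        pca = spca.fit_pca(_frame(rng, p=3))
        with pytest.raises(ValueError, match="betas"):
            spca.RiskModel(disease="AD", T=1.0, m=2, pca=pca, betas=np.ones(3))
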
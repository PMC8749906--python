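"""Correlation-matrix PCA, component selection, residual distances and
diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disfluency import (ResidualDistanceExtractor, ZeroVarianceError,
                        analyze, extract_features, factor_loadings,
                        fit_pca, generate_lowrank_filterbank,
                        generate_utterance, project, reconstruct,
                        residual_distances, select_components, standardize,
                        variable_contributions)


def _svd_oracle(Z):
    """Independent eigenpair computation from the SVD of Z/sqrt(d-1)."""
    d = Z.shape[0]
    U, s, Vt = np.linalg.svd(Z / np.sqrt(d - 1), full_matrices=True)
    evals = np.zeros(Z.shape[1])
    evals[: len(s)] = s**2
    return evals, Vt.T


class TestStandardize:
    def test_hand_example(self):
        out = standardize(np.array([[0.0, 10.0], [2.0, 30.0]]))
        assert np.allclose(out.Z, [[-0.7071, -0.7071], [0.7071, 0.7071]],
                           atol=1e-4)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_columns_zero_mean_unit_sd(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 5)) * rng.uniform(0.5, 20, 5) \
            + rng.uniform(-5, 5, 5)
        out = standardize(X)
        assert np.allclose(out.Z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(out.Z.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_constant_column_raises_naming_it(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        X[:, 1] = 7.0
        with pytest.raises(ZeroVarianceError, match="1"):
            standardize(X)


class TestFitPCA:
    def test_trace_equals_m(self, rng):
        Z = standardize(rng.normal(size=(60, 21)))
        model = fit_pca(Z)
        assert model.eigenvalues.sum() == pytest.approx(21.0, abs=1e-6)

    def test_two_perfectly_correlated_variables(self, rng):
        x = rng.normal(size=50)
        Z = standardize(np.c_[x, 3 * x + 1])
        model = fit_pca(Z)
        assert np.allclose(model.eigenvalues, [2.0, 0.0], atol=1e-10)

    @pytest.mark.parametrize("seed", range(100))
    def test_svd_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(10, 201))
        m = int(rng.integers(2, 22))
        Z = standardize(rng.normal(size=(d, m))).Z
        model = fit_pca(Z)
        evals, evecs = _svd_oracle(Z)
        assert np.allclose(model.eigenvalues, evals, atol=1e-8)
        # eigenvectors agree up to sign on non-degenerate spectra
        for i in range(min(d - 1, m)):
            dot = abs(evecs[:, i] @ model.eigenvectors[:, i])
            assert dot == pytest.approx(1.0, abs=1e-6)

    def test_eigenvectors_orthonormal(self, rng):
        model = fit_pca(standardize(rng.normal(size=(40, 8))))
        E = model.eigenvectors
        assert np.allclose(E.T @ E, np.eye(8), atol=1e-8)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            fit_pca(np.array([[np.nan, 1.0], [0.0, 1.0]]))


class TestSelectComponents:
    @pytest.mark.parametrize("eigenvalues,expected", [
        ([2.0, 1.2, 0.5, 0.3], 2),
        ([1.4, 1.2, 1.1, 0.3], 3),
        ([2.9, 0.5, 0.4, 0.2], 2),
    ])
    def test_hand_examples(self, eigenvalues, expected):
        assert select_components(eigenvalues) == expected

    def test_rejects_empty_and_invalid(self):
        with pytest.raises(ValueError):
            select_components([])
        with pytest.raises(ValueError):
            select_components([0.5, 1.0])  # ascending

    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_within_bounds(self, values):
        ev = np.sort(np.asarray(values))[::-1]
        l = select_components(ev)
        assert 1 <= l <= len(ev)
        # cumulative variance criterion is met
        assert ev[:l].sum() / ev.sum() >= 0.75 - 1e-9 or \
            l == np.sum(ev > 1.0)


class TestProjectReconstruct:
    def test_full_rank_round_trip(self, rng):
        Z = standardize(rng.normal(size=(30, 6)))
        model = fit_pca(Z)
        Y = reconstruct(project(Z, model, 6), model)
        assert np.allclose(Y, Z.Z, atol=1e-8)

    def test_scores_uncorrelated_with_eigenvalue_variance(self, rng):
        Z = standardize(rng.normal(size=(100, 7)))
        model = fit_pca(Z)
        G = project(Z, model, 7)
        cov = np.cov(G.T)
        assert np.allclose(cov, np.diag(model.eigenvalues), atol=1e-6)

    def test_residual_orthogonal_to_retained_eigenvectors(self, rng):
        Z = standardize(rng.normal(size=(50, 6)))
        model = fit_pca(Z)
        l = 3
        resid = Z.Z - reconstruct(project(Z, model, l), model)
        assert np.allclose(resid @ model.eigenvectors[:, :l], 0, atol=1e-8)

    def test_l_out_of_range(self, rng):
        Z = standardize(rng.normal(size=(20, 4)))
        model = fit_pca(Z)
        with pytest.raises(ValueError):
            project(Z, model, 5)


class TestResidualDistances:
    def test_hand_value(self):
        Z = np.array([[0.3, -0.4, 0.0]])
        Y = np.zeros((1, 3))
        out = residual_distances(Z, Y, m=3, l=1)
        assert out.d[0] == pytest.approx(np.sqrt(0.25 / 2), abs=1e-12)

    def test_in_span_observations_score_zero(self, rng):
        # rank-2 data reconstructed with l=2 lies exactly in the model
        W = rng.normal(size=(20, 2))
        B = rng.normal(size=(2, 5))
        Z = standardize(W @ B)
        model = fit_pca(Z)
        Y = reconstruct(project(Z, model, 2), model)
        out = residual_distances(Z, Y, m=5, l=2)
        assert np.all(out.d >= 0)
        assert np.max(out.d) < 1e-8

    def test_rejects_exhausted_dof(self, rng):
        Z = standardize(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            residual_distances(Z, Z.Z, m=3, l=3)


class TestDiagnostics:
    def test_loadings_equal_variable_score_correlations(self, rng):
        Z = standardize(rng.normal(size=(80, 6)))
        model = fit_pca(Z)
        A = factor_loadings(model)
        G = project(Z, model, 6)
        for i in range(6):
            for j in range(6):
                if model.eigenvalues[i] < 1e-12:
                    continue
                r = np.corrcoef(Z.Z[:, j], G[:, i])[0, 1]
                assert A[j, i] == pytest.approx(r, abs=1e-6)

    def test_loadings_of_perfectly_correlated_pair(self, rng):
        x = rng.normal(size=40)
        model = fit_pca(standardize(np.c_[x, 2 * x]))
        assert np.allclose(np.abs(factor_loadings(model, 1)[:, 0]), 1.0,
                           atol=1e-8)

    def test_communality_at_full_rank(self, rng):
        model = fit_pca(standardize(rng.normal(size=(50, 5))))
        A = factor_loadings(model)
        assert np.allclose((A**2).sum(axis=1), 1.0, atol=1e-8)

    def test_contributions_full_rank_and_bounds(self, rng):
        Z = standardize(rng.normal(size=(60, 5)))
        model = fit_pca(Z)
        Y = reconstruct(project(Z, model, 5), model)
        assert np.allclose(variable_contributions(Z, Y), 1.0, atol=1e-9)
        Y2 = reconstruct(project(Z, model, 2), model)
        S = variable_contributions(Z, Y2)
        assert np.all(S >= -1e-9) and np.all(S <= 1 + 1e-9)

    def test_pure_noise_variable_contributes_nothing(self):
        """A variable independent of the retained structure has
        contribution ~0 at d=171."""
        rng = np.random.default_rng(7)
        w = rng.normal(size=(171, 2))
        # balanced two-factor structure so both structural eigenvalues
        # clearly dominate the lone noise variable
        B = np.array([[1.0, 1.0, 1.0, 0.0, 0.0],
                      [0.0, 0.0, 1.0, 1.0, 1.0]])
        X = np.c_[w @ B + 0.01 * rng.normal(size=(171, 5)),
                  rng.normal(size=171)]
        Z = standardize(X)
        model = fit_pca(Z)
        Y = reconstruct(project(Z, model, 2), model)
        S = variable_contributions(Z, Y)
        assert abs(S[-1]) < 0.1

    def test_variance_bookkeeping(self, rng):
        """Retained-eigenvalue share equals the complement of the mean
        residual variance."""
        Z = standardize(rng.normal(size=(90, 8)))
        model = fit_pca(Z)
        for l in (2, 5):
            Y = reconstruct(project(Z, model, l), model)
            resid_var = np.var(Z.Z - Y, axis=0, ddof=1)
            assert model.eigenvalues[:l].sum() / 8 == pytest.approx(
                1 - resid_var.mean(), abs=1e-6)


class TestExtractFeatures:
    def test_shape_and_determinism(self, small_matrices):
        out = extract_features(small_matrices[0])
        assert out.d.shape == (171,)
        assert out.l_used == 4 and out.m_used == 21
        again = extract_features(small_matrices[0])
        assert np.array_equal(out.d, again.d)

    def test_silence_frames_closest_to_model(self):
        """In a block utterance, the silent lead-in sits nearer the PCA
        model than the plosive burst frames."""
        u = generate_utterance("block", seed=2)
        m = analyze(u)
        d = extract_features(m).d
        fd = m.frame_duration
        silence = d[: int(1.2 / fd)]
        burst = d[int(1.30 / fd): int(1.40 / fd) + 1]
        assert silence.mean() < burst.mean()

    def test_mean_distance_monotone_in_l(self):
        fb = generate_lowrank_filterbank(seed=5)
        means = []
        for l in range(1, 21):
            means.append(extract_features(fb, l_override=l).d.mean())
        assert np.all(np.diff(means) <= 1e-12)

    def test_auto_selection_path(self):
        fb = generate_lowrank_filterbank(seed=9)
        out = extract_features(fb, l_override=None)
        assert out.l_used == 4


class TestResidualDistanceExtractor:
    def test_transform_shape(self, small_matrices):
        F = ResidualDistanceExtractor().fit(small_matrices) \
            .transform(small_matrices)
        assert F.shape == (len(small_matrices), 171)
        assert np.all(F >= 0)

    def test_pooled_mode(self, small_matrices):
        ext = ResidualDistanceExtractor(per_utterance=False, n_components=4)
        F = ext.fit(small_matrices).transform(small_matrices)
        assert F.shape == (len(small_matrices), 171)
        assert ext.pooled_model_.eigenvalues.sum() == pytest.approx(
            21.0, abs=1e-6)

    def test_sklearn_params_round_trip(self):
        ext = ResidualDistanceExtractor(n_components=3)
        assert ext.get_params()["n_components"] == 3
        ext.set_params(n_components=None)
        assert ext.n_components is None
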
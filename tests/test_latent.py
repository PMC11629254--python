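"""PCA / PLS-DA / OPLS-DA against independent oracles, plus VIP identities."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as SkPCA

from lipidauth.latent import fit_oplsda, fit_pca, fit_plsda, vip_scores
from lipidauth.preprocess import autoscale
from tests.conftest import two_group_table

RNG = np.random.default_rng(42)


def _align_signs(A, B):
    """Flip columns of B to match the sign convention of A."""
    signs = np.sign(np.sum(A * B, axis=0))
    signs[signs == 0] = 1.0
    return B * signs


class TestPCA:
    def test_collinear_data_single_component(self):
        t = np.linspace(-1, 1, 8)
        X = np.column_stack([2 * t, -3 * t])
        model = fit_pca(X, n_components=2)
        assert model.explained_x_variance[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        X = RNG.normal(size=(10, 6))
        model = fit_pca(X, n_components=4)
        # independent oracle: eigendecomposition of the covariance matrix
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / X.shape[0])
        order = np.argsort(evals)[::-1]
        oracle = evecs[:, order[:4]]
        np.testing.assert_allclose(
            model.loadings, _align_signs(model.loadings, oracle), atol=1e-10
        )
        np.testing.assert_allclose(
            model.explained_x_variance,
            (evals[order] / evals.sum())[:4],
            atol=1e-12,
        )

    def test_agrees_with_sklearn(self):
        X = RNG.normal(size=(12, 7))
        model = fit_pca(X, n_components=3)
        sk = SkPCA(n_components=3).fit(X)
        np.testing.assert_allclose(
            model.loadings, _align_signs(model.loadings, sk.components_.T), atol=1e-10
        )

    def test_duplicating_samples_preserves_directions(self):
        X = RNG.normal(size=(9, 5))
        m1 = fit_pca(X, 2)
        m2 = fit_pca(np.vstack([X, X]), 2)
        np.testing.assert_allclose(m1.loadings, _align_signs(m1.loadings, m2.loadings), atol=1e-8)

    def test_variance_fractions_monotone_and_bounded(self):
        X = RNG.normal(size=(15, 6))
        ev = fit_pca(X, 6).explained_x_variance
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() <= 1 + 1e-12

    def test_rank_truncation_warns(self):
        X = np.tile(RNG.normal(size=(1, 4)), (5, 1)) + np.outer(RNG.normal(size=5), np.ones(4))
        with pytest.warns(UserWarning, match="rank"):
            model = fit_pca(X, n_components=4)
        assert model.n_components < 4


class TestPLSDA:
    def test_single_feature_unit_weight(self):
        X = np.array([[0.0], [0.1], [-0.1], [5.0], [5.1], [4.9]])
        y = ["a", "a", "a", "b", "b", "b"]
        model = fit_plsda(X, y, n_components=1)
        assert abs(model.weights[0, 0]) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_plsda(RNG.normal(size=(4, 3)), ["a"] * 4)

    def test_deflation_shrinks_x(self):
        X = RNG.normal(size=(12, 6))
        y = ["a", "b"] * 6
        Xc = X - X.mean(axis=0)
        norm0 = np.linalg.norm(Xc)
        model = fit_plsda(X, y, n_components=3)
        # reconstruct residual norms from scores/loadings
        E = Xc.copy()
        for a in range(3):
            E = E - np.outer(model.scores[:, a], model.loadings[:, a])
            assert np.linalg.norm(E) < norm0
            norm0 = np.linalg.norm(E)

    def test_deterministic(self):
        X = RNG.normal(size=(10, 8))
        y = ["a", "b"] * 5
        m1 = fit_plsda(X, y, 2)
        m2 = fit_plsda(X, y, 2)
        np.testing.assert_allclose(m1.scores, m2.scores, atol=1e-10)

    def test_first_component_matches_sklearn_pls(self):
        X = RNG.normal(size=(14, 9))
        y = np.array([0, 1] * 7)
        model = fit_plsda(X, y, n_components=1)
        sk = PLSRegression(n_components=1, scale=False).fit(X, (y - y.mean())[:, None])
        w_sk = sk.x_weights_[:, 0]
        w = model.weights[:, 0]
        assert min(np.linalg.norm(w - w_sk), np.linalg.norm(w + w_sk)) < 1e-8

    def test_recovers_planted_markers(self):
        table = two_group_table(
            np.random.default_rng(5), n_lipids=30, shift=np.r_[np.full(3, 5.0), np.zeros(27)]
        )
        scaled, _ = autoscale(table)
        model = fit_plsda(scaled, table.nx_labels().to_numpy(), 1)
        top = np.argsort(-np.abs(model.weights[:, 0]))[:3]
        assert set(top) == {0, 1, 2}


class TestOPLSDA:
    def test_reduces_to_pls_without_orthogonal_structure(self):
        # X essentially rank-1 along y: negligible y-orthogonal variation
        rng = np.random.default_rng(1)
        y = np.array([0.0, 0, 0, 1, 1, 1])
        X = np.outer(y - y.mean(), rng.normal(size=5))
        X += 1e-7 * rng.normal(size=X.shape)  # lift the rank without adding structure
        opls = fit_oplsda(X, ["a", "a", "a", "b", "b", "b"], n_orthogonal=1)
        pls = fit_plsda(X, ["a", "a", "a", "b", "b", "b"], n_components=1)
        t_o, t_p = opls.scores[:, 0], pls.scores[:, 0]
        assert min(np.linalg.norm(t_o - t_p), np.linalg.norm(t_o + t_p)) < 1e-4

    def test_orthogonal_component_absorbs_constructed_direction(self):
        rng = np.random.default_rng(11)
        y = np.array([0.0] * 8 + [1.0] * 8)
        d_pred = np.zeros(10)
        d_pred[0] = 1.0
        d_orth = np.zeros(10)
        d_orth[1] = 1.0
        confound = rng.normal(size=16)
        confound -= confound.mean()
        confound -= (y - y.mean()) * (confound @ (y - y.mean())) / np.sum((y - y.mean()) ** 2)
        X = np.outer(y - y.mean(), d_pred) + 8.0 * np.outer(confound, d_orth)
        X += 0.01 * rng.normal(size=X.shape)
        labels = ["a"] * 8 + ["b"] * 8
        model = fit_oplsda(X, labels, n_orthogonal=1)
        # orthogonal weight concentrates on the confounded coordinate
        assert np.argmax(np.abs(model.orthogonal_weights[:, 0])) == 1
        # predictive scores still separate the classes cleanly
        t = model.scores[:, 0]
        assert abs(t[:8].mean() - t[8:].mean()) > 5 * (t[:8].std() + t[8:].std() + 1e-12)

    def test_orthogonal_scores_uncorrelated_with_y(self):
        table = two_group_table(np.random.default_rng(3), n_lipids=12, shift=np.r_[4.0, np.zeros(11)])
        scaled, _ = autoscale(table)
        y = (table.nx_labels() == "NX").to_numpy(float)
        model = fit_oplsda(scaled, table.nx_labels().to_numpy(), n_orthogonal=2)
        for k in range(model.orthogonal_scores.shape[1]):
            r = np.corrcoef(model.orthogonal_scores[:, k], y)[0, 1]
            assert abs(r) < 1e-8

    def test_separation_at_least_pls_component_one(self, default_table):
        sub = default_table.subset(part="LT", biological_only=True)
        scaled, _ = autoscale(sub)
        labels = sub.nx_labels().to_numpy()
        y = (labels == "NX").astype(float)

        def ratio(t):
            between = (t[y == 1].mean() - t[y == 0].mean()) ** 2
            within = t[y == 1].var() + t[y == 0].var()
            return between / within

        opls = fit_oplsda(scaled, labels, 1)
        pls = fit_plsda(scaled, labels, 1)
        assert ratio(opls.scores[:, 0]) >= ratio(pls.scores[:, 0]) - 1e-9

    def test_too_many_orthogonal_components_rejected(self):
        X = RNG.normal(size=(5, 3))
        with pytest.raises(ValueError, match="rank"):
            fit_oplsda(X, ["a", "a", "b", "b", "b"], n_orthogonal=10)


class TestVIP:
    def test_equal_weights_give_unit_vip(self):
        p = 6
        X = np.tile(np.array([[1.0], [-1.0]] * 3), (1, p))
        y = ["a", "b"] * 3
        model = fit_plsda(X, y, 1)
        vip = vip_scores(model).vip
        np.testing.assert_allclose(vip, np.ones(p), atol=1e-8)

    @pytest.mark.parametrize("n_components", [1, 2, 3])
    def test_mean_square_identity(self, n_components):
        X = RNG.normal(size=(16, 10))
        y = ["a", "b"] * 8
        model = fit_plsda(X, y, n_components)
        vip = vip_scores(model).vip
        assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-8)

    def test_planted_markers_exceed_threshold(self, screen_lt, default_spec):
        lt_markers = [m.lipid_id for m in default_spec.markers if m.scope in ("both", "LT")]
        vips = screen_lt.table["vip"]
        assert (vips[lt_markers] > 1.6).all()

    def test_vip_requires_supervised_model(self):
        model = fit_pca(RNG.normal(size=(6, 4)), 2)
        with pytest.raises(ValueError):
            vip_scores(model)
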
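"""PCA decomposition, Hotelling ellipses, component removal, loading selection."""

import numpy as np
import pandas as pd
import pytest

import chemometab as cm
from chemometab.pca import PCAError


def autoscaled(rng, n=30, p=8):
    X = rng.standard_normal((n, p))
    Z, _, _ = cm.autoscale(X)
    return Z


class TestFitPCA:
    def test_explained_fractions_sum_to_one_at_full_rank(self, rng):
        X = rng.standard_normal((10, 2))
        X -= X.mean(axis=0)
        m = cm.fit_pca(X, 2)
        assert m.explained_fraction.sum() == pytest.approx(1.0, abs=1e-8)

    def test_loadings_orthonormal_and_fractions_non_increasing(self, rng):
        Z = autoscaled(rng)
        m = cm.fit_pca(Z, 5)
        assert np.allclose(m.loadings.T @ m.loadings, np.eye(5), atol=1e-8)
        assert np.all(np.diff(m.explained_fraction) <= 1e-12)
        # scores columns mutually orthogonal
        G = m.scores.T @ m.scores
        assert np.allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_duplicated_features_get_equal_loadings(self, rng):
        Z = autoscaled(rng, p=5)
        Zdup = np.hstack([Z, Z[:, [0]]])
        m = cm.fit_pca(Zdup, 3)
        assert np.allclose(m.loadings[0], m.loadings[-1], atol=1e-8)

    def test_two_feature_correlation_closed_form(self, rng):
        """For two autoscaled features with correlation rho, the eigenvalues
        are (1 +- rho)/2 and PC1 is the (1,1)/sqrt(2) direction."""
        rho = 0.99
        n = 200_000
        z = rng.standard_normal((n, 2))
        X = np.hstack([z[:, [0]], rho * z[:, [0]] + np.sqrt(1 - rho**2) * z[:, [1]]])
        Z, _, _ = cm.autoscale(X)
        m = cm.fit_pca(Z, 2)
        assert m.explained_fraction[0] == pytest.approx((1 + rho) / 2, abs=2e-3)
        assert abs(m.loadings[:, 0] @ (np.ones(2) / np.sqrt(2))) == pytest.approx(1.0, abs=1e-3)

    def test_deterministic_sign_convention(self, rng):
        Z = autoscaled(rng)
        m = cm.fit_pca(Z, 4)
        for a in range(4):
            assert m.loadings[np.argmax(np.abs(m.loadings[:, a])), a] > 0

    def test_component_count_validation(self, rng):
        Z = autoscaled(rng, n=6, p=10)
        with pytest.raises(PCAError):
            cm.fit_pca(Z, 6)  # > n-1
        rank2 = np.outer(rng.standard_normal(8), rng.standard_normal(4))
        rank2 += np.outer(rng.standard_normal(8), rng.standard_normal(4))
        rank2 -= rank2.mean(axis=0)
        with pytest.raises(PCAError):
            cm.fit_pca(rank2, 4)  # > rank after centering


class TestHotellingEllipse:
    def test_vanishing_confidence_shrinks_axes(self, rng):
        Y = rng.standard_normal((50, 2))
        small = cm.hotelling_ellipse(Y, 1e-9)
        big = cm.hotelling_ellipse(Y, 0.95)
        assert np.all(small.semi_axes < 1e-3 * big.semi_axes)

    def test_isotropic_scores_give_equal_axes(self):
        # exactly identity covariance by construction
        Y = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]]) * np.sqrt(3.0 / 2.0)
        e = cm.hotelling_ellipse(Y, 0.95)
        assert e.semi_axes[0] == pytest.approx(e.semi_axes[1])

    def test_monte_carlo_coverage(self, rng):
        pts = rng.standard_normal((100_000, 2))
        e = cm.hotelling_ellipse(pts, 0.95)
        assert e.contains(pts).mean() == pytest.approx(0.95, abs=0.005)

    def test_small_n_and_singular_covariance_rejected(self, rng):
        with pytest.raises(PCAError):
            cm.hotelling_ellipse(rng.standard_normal((3, 2)), 0.95)
        line = np.outer(np.arange(6, dtype=float), [1.0, 2.0])
        with pytest.raises(PCAError):
            cm.hotelling_ellipse(line, 0.95)

    def test_group_ellipses_computed_independently(self, rng):
        scores = rng.standard_normal((40, 2))
        classes = np.repeat(["A", "B"], 20)
        scores[20:] += 10
        both = cm.group_ellipses(scores, classes)
        alone = cm.hotelling_ellipse(scores[:20], 0.95)
        assert np.allclose(both["A"].center, alone.center)
        assert np.allclose(both["A"].semi_axes, alone.semi_axes)


class TestReconstruction:
    def test_empty_drop_is_identity(self, rng):
        Z = autoscaled(rng)
        m = cm.fit_pca(Z, 3)
        assert np.allclose(cm.remove_components_and_reconstruct(Z, m, set()), Z)

    def test_dropping_one_component_of_rank2_leaves_rank1(self, rng):
        A = np.outer(rng.standard_normal(20), rng.standard_normal(6))
        B = np.outer(rng.standard_normal(20), rng.standard_normal(6))
        X = A + B
        X -= X.mean(axis=0)
        m = cm.fit_pca(X, 2)
        Xr = cm.remove_components_and_reconstruct(X, m, {2})
        s = np.linalg.svd(Xr, compute_uv=False)
        assert s[1] < 1e-10 * s[0]

    def test_projection_onto_dropped_loading_is_zero(self, rng):
        Z = autoscaled(rng)
        m = cm.fit_pca(Z, 4)
        Zr = cm.remove_components_and_reconstruct(Z, m, {2, 4})
        for d in (2, 4):
            assert np.abs(Zr @ m.loadings[:, d - 1]).max() < 1e-10

    def test_pythagoras_energy_split(self, rng):
        Z = autoscaled(rng)
        m = cm.fit_pca(Z, 3)
        Zr = cm.remove_components_and_reconstruct(Z, m, {1, 3})
        dropped = sum(np.linalg.norm(m.scores[:, d - 1]) ** 2 for d in (1, 3))
        assert np.linalg.norm(Z) ** 2 == pytest.approx(np.linalg.norm(Zr) ** 2 + dropped)

    def test_refit_never_rediscovers_dropped_direction(self):
        cfg = cm.SimulationConfig(
            seed=3, batch_sd=1.0, effect_size=0.15, noise_sd=0.1, dilution_range=(1, 1)
        )
        table, truth = cm.generate_dataset(cfg)
        pre, _ = cm.preprocess_table(table)
        Z = pre.values()
        m = cm.fit_pca(Z, 5)
        batch_pc = int(np.argmax(np.abs(m.loadings.T @ truth.batch_loading))) + 1
        Zr = cm.remove_components_and_reconstruct(Z, m, {batch_pc})
        refit = cm.fit_pca(Zr, 4)
        assert np.abs(refit.loadings.T @ m.loadings[:, batch_pc - 1]).max() < 0.05
        assert np.abs(refit.loadings.T @ truth.batch_loading).max() < 0.2

    def test_batch_removal_does_not_hurt_class_separation(self):
        cfg = cm.SimulationConfig(seed=3, batch_sd=1.2, effect_size=0.8, noise_sd=0.1)
        table, truth = cm.generate_dataset(cfg)
        pre, _ = cm.preprocess_table(table)
        Z = pre.values()
        m = cm.fit_pca(Z, 5)
        batch_pc = int(np.argmax(np.abs(m.loadings.T @ truth.batch_loading))) + 1
        Zr = cm.remove_components_and_reconstruct(Z, m, {batch_pc})
        y = pre.classes.to_numpy()

        def separation(M):
            scores = cm.fit_pca(M, 2).scores
            grand = scores.mean(axis=0)
            within = between = 0.0
            for c in np.unique(y):
                sc = scores[y == c]
                between += len(sc) * np.sum((sc.mean(axis=0) - grand) ** 2)
                within += np.sum((sc - sc.mean(axis=0)) ** 2)
            return between / within

        assert separation(Zr) >= separation(Z)


class TestAverageReplicates:
    def _table(self, X, classes, bio):
        n, p = X.shape
        meta = pd.DataFrame(
            {
                "class": classes,
                "bio_rep": bio,
                "tech_rep": list(range(1, n + 1)),
                "qc": [False] * n,
                "injection_order": list(range(1, n + 1)),
            },
            index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
        )
        intens = pd.DataFrame(
            X, index=meta.index, columns=pd.Index([f"F{j}" for j in range(p)], name="feature_id")
        )
        return cm.FeatureTable(intens, meta)

    def test_identical_replicates_average_to_themselves(self):
        X = np.tile([1.0, 2.0, 3.0], (2, 1))
        t = self._table(X, ["CTRL", "CTRL"], ["b1", "b1"])
        avg = cm.average_replicates(t)
        assert np.allclose(avg.intensities.to_numpy()[0], [1, 2, 3])

    def test_arithmetic_mean(self):
        t = self._table(np.array([[1.0], [3.0]]), ["CTRL", "CTRL"], ["b1", "b1"])
        assert cm.average_replicates(t).intensities.iloc[0, 0] == 2.0

    def test_conflicting_class_labels_rejected(self):
        t = self._table(np.ones((2, 2)), ["CTRL", "M"], ["b1", "b1"])
        with pytest.raises(PCAError, match="conflicting"):
            cm.average_replicates(t)

    def test_averaging_commutes_with_reconstruction_when_scores_shared(self, rng):
        """If replicate partners share the dropped-component score, removing
        the component then averaging equals averaging then removing."""
        p = 6
        load = rng.standard_normal(p)
        load /= np.linalg.norm(load)
        base = rng.standard_normal((3, p))
        scores = rng.standard_normal(3)
        rows = np.repeat(base, 2, axis=0) + np.outer(np.repeat(scores, 2), load)
        rows += rng.standard_normal((6, p)) * 0.0  # replicates identical apart from shared score
        groups = np.repeat([f"b{i}" for i in range(3)], 2)
        removed = rows - np.outer(rows @ load, load)
        avg_then_remove = np.array([removed[groups == g].mean(axis=0) for g in dict.fromkeys(groups)])
        averaged = np.array([rows[groups == g].mean(axis=0) for g in dict.fromkeys(groups)])
        remove_then_avg = averaged - np.outer(averaged @ load, load)
        assert np.allclose(avg_then_remove, remove_then_avg)


class TestSelectLoadings:
    def _model(self, p1, p2):
        P = np.column_stack([p1, p2]).astype(float)
        return cm.PCAModel(
            scores=np.zeros((3, 2)),
            loadings=P,
            explained_fraction=np.array([0.6, 0.3]),
            n_components=2,
        )

    def test_threshold_relative_to_component_maximum(self):
        m = self._model([1.0, 0.6, 0.4], [0.0, 0.0, 0.0])
        sel = cm.select_loadings(m, ["a", "b", "c"], rel_threshold=0.5)
        assert sel.feature_ids == ["a", "b"]

    def test_quadrant_symbols_follow_loading_signs(self):
        m = self._model([0.9, -0.9, 0.9, -0.9], [0.8, -0.8, -0.8, 0.8])
        sel = cm.select_loadings(m, ["pp", "nn", "pn", "np"], rel_threshold=0.5)
        assert sel.quadrants == {"pp": "up", "nn": "down", "pn": "right", "np": "left"}

    def test_published_sign_pattern_maps_left(self):
        """A feature loading negatively on PC1 and positively on PC2 (the
        hypotaurine pattern, -0.00319 / +0.00044) is a left-facing marker."""
        m = self._model([-0.003185744, 0.9], [0.000440457, 0.9])
        sel = cm.select_loadings(m, ["hypotaurine", "other"], rel_threshold=0.001)
        assert sel.quadrants["hypotaurine"] == "left"

    def test_associated_class_is_largest_magnitude_group_mean(self):
        m = self._model([1.0, 0.9], [0.5, -0.5])
        class_means = pd.DataFrame(
            {"a": [2.0, -0.1], "b": [0.3, -3.0]}, index=["CTRL", "M"]
        )
        sel = cm.select_loadings(m, ["a", "b"], 0.5, class_means=class_means)
        assert sel.associated_class == {"a": "CTRL", "b": "M"}

    def test_all_zero_loadings_give_empty_selection(self):
        m = self._model([0.0, 0.0], [0.0, 0.0])
        sel = cm.select_loadings(m, ["a", "b"], 0.5)
        assert sel.feature_ids == []


def test_rank_components_by_correlation_orders_batch_first():
    cfg = cm.SimulationConfig(seed=3, batch_sd=1.0, effect_size=0.15, noise_sd=0.1)
    table, truth = cm.generate_dataset(cfg)
    pre, _ = cm.preprocess_table(table)
    m = cm.fit_pca(pre.values(), 5)
    ranking = cm.rank_components_by_correlation(m, truth.batch_scores)
    assert ranking.iloc[0]["component"] == 1
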
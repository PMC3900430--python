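"""Windowed rate vectors, PCA, and the cluster-geometry quantifications."""

import numpy as np
import pytest

from lptcnet import population_pca as ppca
from lptcnet.population_pca import (PCAResult, RateMatrix, SPIKING_ORDER,
                                    cluster_geometry, component_identity,
                                    contribution_gap, rate_vectors, run_pca)
from lptcnet.spike_analysis import SpikeTrain


def _trains(times_by_cell, duration):
    return {c: SpikeTrain(c, np.asarray(times_by_cell.get(c, [])), duration)
            for c in SPIKING_ORDER}


class TestRateVectors:
    def test_24s_train_gives_160_windows(self):
        trains = _trains({}, 24000.0)
        m = rate_vectors(trains, 150.0)
        assert m.rates.shape == (160, 6)

    def test_empty_trains_all_zero(self):
        m = rate_vectors(_trains({}, 3000.0), 150.0)
        assert np.all(m.rates == 0.0)

    def test_column_sums_conserve_spike_counts(self):
        rng = np.random.default_rng(0)
        times = {c: np.unique(np.sort(rng.uniform(0, 2990, 60)))
                 for c in SPIKING_ORDER}
        m = rate_vectors(_trains(times, 3000.0), 150.0)
        for j, c in enumerate(SPIKING_ORDER):
            in_range = np.count_nonzero(times[c] < m.rates.shape[0] * 150.0)
            assert m.rates[:, j].sum() * 0.15 == pytest.approx(in_range)

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError):
            rate_vectors(_trains({}, 100.0), 150.0)


def _matrix(data, labels=None):
    data = np.asarray(data, dtype=float)
    labels = labels if labels is not None else np.zeros(len(data))
    return RateMatrix(data, 150.0, np.asarray(labels))


class TestRunPCA:
    def test_single_axis_data_has_unit_first_ratio(self):
        rng = np.random.default_rng(1)
        x = np.zeros((50, 6))
        x[:, 2] = rng.normal(10.0, 3.0, 50)
        res = run_pca(_matrix(x), mode="covariance")
        assert res.contribution_ratios[0] == pytest.approx(1.0)

    def test_isotropic_data_ratios_near_uniform(self):
        rng = np.random.default_rng(2)
        n = 20000
        res = run_pca(_matrix(rng.normal(5.0, 1.0, (n, 6))))
        assert np.allclose(res.contribution_ratios, 1 / 6, atol=2.5 / np.sqrt(n))

    def test_components_orthonormal_and_ratios_sum_to_one(self):
        rng = np.random.default_rng(3)
        res = run_pca(_matrix(rng.gamma(2.0, 3.0, (200, 6))))
        assert np.allclose(res.components @ res.components.T, np.eye(6),
                           atol=1e-10)
        assert res.contribution_ratios.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(res.contribution_ratios) <= 1e-12)

    def test_full_reconstruction_identity(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.0, 2.0, (40, 6)) + rng.normal(3.0, 1.0, 6)
        res = run_pca(_matrix(x), mode="covariance")
        centered = x - x.mean(axis=0)
        scores = centered @ res.components.T
        assert np.allclose(scores @ res.components + x.mean(axis=0), x,
                           atol=1e-9)

    def test_matches_sklearn_covariance_oracle(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (300, 6)) @ np.diag([3, 2, 1.5, 1, 0.5, 0.2])
        res = run_pca(_matrix(x), mode="covariance")
        sk = sklearn.PCA(n_components=6).fit(x)
        assert np.allclose(res.contribution_ratios,
                           sk.explained_variance_ratio_, atol=1e-8)
        for k in range(6):
            dot = abs(float(res.components[k] @ sk.components_[k]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_zero_variance_column_falls_back_to_covariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, (50, 6))
        x[:, 0] = 7.0
        with pytest.warns(UserWarning):
            res = run_pca(_matrix(x), mode="correlation")
        assert res.mode == "covariance"

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, (80, 6))
        a = run_pca(_matrix(x))
        b = run_pca(_matrix(x))
        assert np.array_equal(a.components, b.components)
        for k in range(6):
            assert a.components[k, np.argmax(np.abs(a.components[k]))] > 0


def _scores_result(scores, labels):
    scores = np.asarray(scores, dtype=float)
    return PCAResult(np.eye(6), np.ones(6), np.full(6, 1 / 6), scores,
                     np.asarray(labels), "correlation")


class TestClusterGeometry:
    def test_diagonal_centroids_fill_quadrants_at_45_degrees(self):
        rng = np.random.default_rng(8)
        scores, labels = [], []
        for s, c in (("C", (1, 1)), ("CC", (-1, -1)), ("FB", (-1, 1)),
                     ("BF", (1, -1))):
            scores.append(np.asarray(c) + rng.normal(0, 0.05, (30, 2)))
            labels += [s] * 30
        geom = cluster_geometry(_scores_result(np.vstack(scores), labels))
        assert geom["quadrant_separation"] == 1.0
        assert geom["axis_alignment"]["in_phase"] == pytest.approx(45.0, abs=2.0)

    def test_axis_aligned_centroids_have_zero_alignment(self):
        scores, labels = [], []
        for s, c in (("C", (1, 0)), ("CC", (-1, 0)), ("FB", (0, 1)),
                     ("BF", (0, -1))):
            scores.append(np.tile(c, (20, 1)).astype(float))
            labels += [s] * 20
        geom = cluster_geometry(_scores_result(np.vstack(scores), labels))
        assert geom["axis_alignment"]["in_phase"] == pytest.approx(0.0, abs=1e-9)
        assert geom["axis_alignment"]["out_of_phase"] == pytest.approx(0.0, abs=1e-9)
        assert geom["quadrant_separation"] == 0.0


class TestComponentIdentity:
    def test_axis_aligned_rotation_contrast_labels_pc1_in_phase(self):
        scores, labels = [], []
        for s, c in (("C", (2, 0)), ("CC", (-2, 0)), ("FB", (0, 1)),
                     ("BF", (0, -1))):
            scores.append(np.tile(c, (20, 1)).astype(float))
            labels += [s] * 20
        ident = component_identity(_scores_result(np.vstack(scores), labels))
        assert ident == {"PC1": "in_phase", "PC2": "out_of_phase"}

    def test_quadrant_geometry_labels_monocular(self):
        # C & BF share the left eye: both on the PC1-positive side
        scores, labels = [], []
        for s, c in (("C", (1, 1)), ("BF", (1, -1)), ("CC", (-1, -1)),
                     ("FB", (-1, 1))):
            scores.append(np.tile(c, (20, 1)).astype(float))
            labels += [s] * 20
        ident = component_identity(_scores_result(np.vstack(scores), labels))
        assert ident["PC1"] == "left_monocular"
        assert ident["PC2"] == "right_monocular"

    def test_ambiguous_orientation_reported_mixed(self):
        # a single cluster pair at 40° from both axes
        scores, labels = [], []
        for s, ang in (("C", 40.0), ("CC", 220.0)):
            c = (np.cos(np.radians(ang)), np.sin(np.radians(ang)))
            scores.append(np.tile(c, (20, 1)).astype(float))
            labels += [s] * 20
        ident = component_identity(_scores_result(np.vstack(scores), labels),
                                   ambiguity_deg=30.0)
        assert ident["PC1"] == "mixed"

    def test_contribution_gap(self):
        res = PCAResult(np.eye(6), np.ones(6),
                        np.array([0.5, 0.3, 0.1, 0.05, 0.03, 0.02]),
                        np.zeros((10, 2)), np.zeros(10), "correlation")
        assert contribution_gap(res) == pytest.approx(0.2)
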
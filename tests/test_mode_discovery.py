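import numpy as np
import pytest

from modewalk import (
    DEFAULT_MODE_PARAMS,
    ModeModel,
    SwitchingConfig,
    annotate_trajectory,
    default_segment_pool,
    feature_matrix,
    fit_modes,
    name_modes,
    scan_cluster_count,
    silhouette,
    simulate_mode_segment,
    simulate_switching_trajectory,
)
from modewalk.errors import AmbiguousNamingError, UndefinedScoreError
from modewalk.features import FEATURE_NAMES


def silhouette_oracle(points, labels):
    """Independent double-loop implementation of the self-inclusive score."""
    points = np.asarray(points, float)
    n = len(points)
    out = np.empty(n)
    for i in range(n):
        by_cluster = {}
        for j in range(n):
            by_cluster.setdefault(labels[j], []).append(
                np.linalg.norm(points[i] - points[j]))
        dw = np.mean(by_cluster[labels[i]])
        dd = min(np.mean(v) for c, v in by_cluster.items() if c != labels[i])
        out[i] = (dd - dw) / max(dw, dd) if max(dw, dd) > 0 else 0.0
    return out


@pytest.fixture(scope="module")
def small_pool():
    """600 constant-mode segments (200 per mode) with ground truth."""
    segs, labels = default_segment_pool(600, seed=77)
    return feature_matrix(segs), np.array(labels)


@pytest.fixture(scope="module")
def small_model(small_pool):
    feats, _ = small_pool
    return fit_modes(feats, k=3, seed=0, cv=3)


class TestSilhouette:
    def test_degenerate_far_clusters_score_one(self):
        pts = np.vstack((np.zeros((5, 2)), np.full((5, 2), 1000.0)))
        labels = np.repeat([0, 1], 5)
        diag = silhouette(pts, labels)
        np.testing.assert_array_equal(diag.scores, 1.0)
        assert diag.mean_score == 1.0

    def test_equal_within_and_neighbor_distance_scores_zero(self):
        # point 0's mean distance within {0,2} equals its distance to {(0,1)}
        pts = np.array([[0, 0], [2, 0], [0, 1.0]])
        diag = silhouette(pts, np.array([0, 0, 1]))
        assert diag.scores[0] == 0.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(40, 5))
        labels = rng.integers(0, 3, 40)
        diag = silhouette(pts, labels)
        np.testing.assert_allclose(diag.scores, silhouette_oracle(pts, labels),
                                   atol=1e-9)

    def test_single_cluster_undefined(self):
        with pytest.raises(UndefinedScoreError):
            silhouette(np.random.default_rng(0).normal(size=(5, 2)), np.zeros(5))


class TestScanClusterCount:
    def test_two_blobs_selects_two(self):
        rng = np.random.default_rng(7)
        pts = np.vstack((rng.normal(0, 1, (100, 5)), rng.normal(20, 1, (100, 5))))
        scores, best = scan_cluster_count(pts, range(2, 7), seed=0)
        assert best == 2
        assert all(-1 <= s <= 1 for s in scores.values())

    def test_default_mixture_selects_three(self, small_pool):
        feats, _ = small_pool
        _, best = scan_cluster_count(feats, range(2, 9), seed=0)
        assert best == 3


class TestFitModes:
    def test_separable_blobs_fully_agree(self):
        rng = np.random.default_rng(8)
        pts = np.vstack((rng.normal(0, 1, (150, 5)), rng.normal(30, 1, (150, 5))))
        model = fit_modes(pts, k=2, seed=0, cv=3)
        assert model.heldout_agreement == 1.0

    def test_cluster_recovery_on_default_mixture(self, small_pool, small_model):
        """K-means pseudo-labels recover simulator ground truth (ARI >= 0.9)."""
        from sklearn.metrics import adjusted_rand_score
        feats, truth = small_pool
        predicted = small_model.predict_clusters(feats)
        assert adjusted_rand_score(truth, predicted) >= 0.9

    def test_training_agreement_at_least_heldout(self, small_model):
        assert small_model.train_agreement >= small_model.heldout_agreement

    def test_deterministic_under_fixed_seed(self, small_pool, small_model):
        feats, _ = small_pool
        again = fit_modes(feats, k=3, seed=0, cv=3)
        assert again.heldout_agreement == small_model.heldout_agreement
        np.testing.assert_array_equal(again.feature_importances,
                                      small_model.feature_importances)
        np.testing.assert_array_equal(again.predict_clusters(feats),
                                      small_model.predict_clusters(feats))

    def test_asphericity_dominates_when_only_it_differs(self):
        """A contrast built purely in asphericity yields it the top importance."""
        rng = np.random.default_rng(9)
        n = 300
        base = np.column_stack([
            rng.normal(10, 1, n), np.r_[rng.normal(0.2, 0.02, n // 2),
                                        rng.normal(0.8, 0.02, n - n // 2)],
            rng.normal(5, 0.5, n), rng.normal(20, 2, n), rng.normal(1, 0.1, n)])
        model = fit_modes(base, k=2, seed=0, cv=3)
        i_asph = FEATURE_NAMES.index("asphericity")
        assert model.feature_importances.argmax() == i_asph


class TestNameModes:
    def test_default_mixture_names_match_ground_truth(self, small_pool, small_model):
        feats, truth = small_pool
        assert small_model.naming is not None
        predicted = np.array(small_model.predict_modes(feats))
        agreement = (predicted == truth).mean()
        assert agreement >= 0.95

    def test_naming_is_a_bijection(self, small_model):
        assert sorted(small_model.naming.values()) == ["FP", "SD", "SP"]

    def test_naming_requires_three_clusters(self):
        rng = np.random.default_rng(10)
        pts = np.vstack((rng.normal(0, 1, (100, 5)), rng.normal(30, 1, (100, 5))))
        model = fit_modes(pts, k=2, seed=0, cv=3)
        with pytest.raises(AmbiguousNamingError):
            name_modes(model, pts)

    def test_fp_has_highest_energy_sp_higher_asphericity(self, small_pool, small_model):
        feats, _ = small_pool
        labels = small_model.predict_clusters(feats)
        i_e = FEATURE_NAMES.index("energy")
        i_a = FEATURE_NAMES.index("asphericity")
        inv = {m: c for c, m in small_model.naming.items()}
        mean_e = {m: feats[labels == c, i_e].mean() for m, c in inv.items()}
        mean_a = {m: feats[labels == c, i_a].mean() for m, c in inv.items()}
        assert mean_e["FP"] == max(mean_e.values())
        assert mean_a["SP"] > mean_a["SD"]


class TestAnnotate:
    def test_pure_fp_trajectory_is_all_fp(self, small_model):
        traj = simulate_mode_segment(DEFAULT_MODE_PARAMS["FP"], 240, seed=3)
        seq = annotate_trajectory(small_model, traj)
        assert len(seq) == 4
        assert set(seq.modes) == {"FP"}

    def test_switching_trajectory_recovered(self, small_model):
        cfg = SwitchingConfig(np.full((3, 3), 1 / 3), duration=12 * 60.0, seed=21)
        hits = total = 0
        for k in range(10):
            cfg.seed = 100 + k
            traj, truth = simulate_switching_trajectory(DEFAULT_MODE_PARAMS, cfg)
            seq = annotate_trajectory(small_model, traj)
            assert len(seq) == len(truth)
            hits += sum(a == b for a, b in zip(seq.modes, truth))
            total += len(truth)
        assert hits / total >= 0.9

    def test_59_point_window_is_classified(self, small_model):
        traj = simulate_mode_segment(DEFAULT_MODE_PARAMS["FP"], 59, seed=4)
        seq = annotate_trajectory(small_model, traj)
        assert len(seq) == 1

    def test_too_short_trajectory_gives_empty_sequence(self, small_model):
        traj = simulate_mode_segment(DEFAULT_MODE_PARAMS["FP"], 30, seed=5)
        assert len(annotate_trajectory(small_model, traj)) == 0


def test_model_roundtrip_through_json(tmp_path, small_pool, small_model):
    feats, _ = small_pool
    path = tmp_path / "model.json"
    small_model.save(path)
    loaded = ModeModel.load(path)
    np.testing.assert_array_equal(loaded.predict_clusters(feats),
                                  small_model.predict_clusters(feats))
    assert loaded.naming == small_model.naming
    assert loaded.heldout_agreement == small_model.heldout_agreement


def test_model_version_mismatch_fails_loudly(tmp_path):
    import json
    path = tmp_path / "bad.json"
    path.write_text(json.dumps({"format": "something-else/9"}))
    from modewalk.errors import ModelIOError
    with pytest.raises(ModelIOError):
        ModeModel.load(path)
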
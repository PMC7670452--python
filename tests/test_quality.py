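"""Channel-quality features, rule and LDOF detection, neighbor repair."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hdsemg import (ArtifactSpec, SimulationConfig, compute_channel_features,
                    detect_outliers_ldof, detect_outliers_rules, ldof_scores,
                    outlier_percent, replace_bad_channels, simulate_recording)
from hdsemg.grids import ElectrodeGrid
from hdsemg.quality import QualityThresholds

FS = 2048.0


def _grid():
    return ElectrodeGrid(array_id=1, n_rows=6, n_cols=16)


class TestChannelFeatures:
    def test_pure_line_channel_has_line_power_near_one(self):
        g = _grid()
        t = np.arange(int(2 * FS)) / FS
        sig = 0.01 * np.random.default_rng(0).standard_normal((96, len(t)))
        sig[7] = np.sin(2 * np.pi * 50.0 * t)
        f = compute_channel_features(sig, g, FS)
        assert f.p_line_rel[7] > 0.99
        assert f.p_line_rel[np.arange(96) != 7].max() < 0.2

    def test_slow_drift_channel_has_low_band_power_near_one(self):
        g = _grid()
        t = np.arange(int(4 * FS)) / FS
        sig = 0.01 * np.random.default_rng(1).standard_normal((96, len(t)))
        sig[30] = np.sin(2 * np.pi * 0.5 * t)
        f = compute_channel_features(sig, g, FS)
        assert f.p_low_rel[30] > 0.99

    def test_duplicated_neighbors_fully_correlated(self):
        g = _grid()
        base = np.random.default_rng(2).standard_normal(int(1 * FS))
        sig = np.tile(base, (96, 1))
        f = compute_channel_features(sig, g, FS)
        assert np.allclose(f.neighbor_xcorr, 1.0, atol=1e-9)

    def test_single_channel_grid_rejected(self):
        g = ElectrodeGrid(array_id=1, n_rows=6, n_cols=16,
                          missing=frozenset(range(1, 96)))
        with pytest.raises(ValueError, match="single-channel"):
            compute_channel_features(np.zeros((1, 2048)), g, FS)


class TestRuleDetection:
    def test_clean_grid_has_no_flags(self):
        rec = simulate_recording(SimulationConfig(seed=21, duration=4.0,
                                                  task="supination", effort=30))
        r = rec.recordings[0]
        rep = detect_outliers_rules(
            compute_channel_features(r.signals, r.grid, r.fs), r.grid)
        assert rep.flagged_channels.size == 0

    @pytest.mark.parametrize("kind,rule", [
        ("dead", "rms"),
        ("line_contam", "p_line"),
        ("lowfreq_transient", "p_low"),
    ])
    def test_single_artifact_flagged_by_its_rule(self, kind, rule):
        cfg = SimulationConfig(seed=22, duration=4.0, task="flexion",
                               effort=30,
                               artifact_specs=(ArtifactSpec(33, kind),))
        rec = simulate_recording(cfg)
        r = rec.recordings[0]
        rep = detect_outliers_rules(
            compute_channel_features(r.signals, r.grid, r.fs), r.grid)
        assert list(rep.flagged_channels) == [33]
        assert rule in rep.rules[33]

    def test_every_flag_lists_a_triggering_rule(self):
        cfg = SimulationConfig(seed=23, duration=4.0,
                               artifact_specs=(ArtifactSpec(5, "dead"),
                                               ArtifactSpec(60, "high_power")))
        rec = simulate_recording(cfg)
        r = rec.recordings[0]
        rep = detect_outliers_rules(
            compute_channel_features(r.signals, r.grid, r.fs), r.grid)
        for ch in rep.flagged_channels:
            assert rep.rules[ch]

    def test_invalid_threshold_spec_rejected(self):
        rec = simulate_recording(SimulationConfig(seed=1, duration=1.0))
        r = rec.recordings[0]
        f = compute_channel_features(r.signals, r.grid, r.fs)
        with pytest.raises(ValueError, match="radius"):
            detect_outliers_rules(f, r.grid,
                                  QualityThresholds(neighborhood_radius=0))


class TestLdof:
    def test_matches_brute_force_pairwise_oracle(self, rng):
        X = rng.normal(size=(20, 4))
        k = 6
        scores = ldof_scores(X, k)
        # independent oracle: explicit loops over pairwise distances
        for i in range(len(X)):
            d = [(np.linalg.norm(X[i] - X[j]), j) for j in range(len(X))
                 if j != i]
            d.sort()
            nn = [j for _, j in d[:k]]
            dbar = np.mean([dd for dd, _ in d[:k]])
            inner = [np.linalg.norm(X[a] - X[b]) for a in nn for b in nn
                     if a != b]
            assert scores[i] == pytest.approx(dbar / np.mean(inner), abs=1e-12)

    def test_coincident_neighbors_score_zero(self):
        X = np.zeros((8, 3))
        X[-1] = [5, 5, 5]
        scores = ldof_scores(X, 4)
        assert scores[0] == 0.0  # coincident cluster point

    def test_far_point_gets_highest_score(self, rng):
        X = rng.normal(0, 0.1, size=(25, 4))
        X[11] += 10.0
        scores = ldof_scores(X, 10)
        assert np.argmax(scores) == 11

    def test_scale_invariance(self, rng):
        X = rng.normal(size=(15, 3))
        assert np.allclose(ldof_scores(X, 5), ldof_scores(7.3 * X, 5))

    def test_k_bounds_enforced(self, rng):
        with pytest.raises(ValueError):
            ldof_scores(rng.normal(size=(5, 2)), 5)

    def test_detects_injected_artifact_unsupervised(self):
        cfg = SimulationConfig(seed=24, duration=4.0,
                               artifact_specs=(ArtifactSpec(50, "dead"),))
        rec = simulate_recording(cfg)
        r = rec.recordings[0]
        rep = detect_outliers_ldof(
            compute_channel_features(r.signals, r.grid, r.fs))
        assert 50 in rep.flagged_channels


class TestRepair:
    def test_bad_channel_amid_constant_neighbors(self):
        v = np.full((4, 5), 3.0)
        v[2, 2] = 99.0
        flags = np.zeros((4, 5), bool)
        flags[2, 2] = True
        out, log = replace_bad_channels(v, flags)
        assert out[2, 2] == pytest.approx(3.0)
        assert log["repaired"] == [(2, 2)]

    def test_interior_channel_equals_neighbor_mean(self):
        v = np.arange(20, dtype=float).reshape(4, 5)
        flags = np.zeros((4, 5), bool)
        flags[1, 2] = True
        out, _ = replace_bad_channels(v, flags)
        nb = [v[r, c] for r in (0, 1, 2) for c in (1, 2, 3)
              if (r, c) != (1, 2)]
        assert out[1, 2] == pytest.approx(np.mean(nb))

    def test_no_flags_is_identity(self):
        v = np.random.default_rng(3).normal(size=(6, 16))
        out, log = replace_bad_channels(v, np.zeros((6, 16), bool))
        assert np.array_equal(out, v) and log["repaired"] == []

    def test_idempotent_on_bad_clusters(self, rng):
        v = rng.normal(size=(6, 16))
        flags = np.zeros((6, 16), bool)
        flags[2:4, 5:8] = True  # a 2x3 cluster
        once, _ = replace_bad_channels(v, flags)
        twice, _ = replace_bad_channels(once, flags)
        assert np.allclose(once, twice, atol=1e-8)

    def test_works_on_time_resolved_grids(self, rng):
        v = rng.normal(size=(4, 4, 50))
        flags = np.zeros((4, 4), bool)
        flags[0, 0] = True
        out, _ = replace_bad_channels(v, flags)
        nb = [v[0, 1], v[1, 0], v[1, 1]]
        assert np.allclose(out[0, 0], np.mean(nb, axis=0))

    def test_all_bad_rejected(self):
        with pytest.raises(ValueError, match="all"):
            replace_bad_channels(np.ones((2, 2)), np.ones((2, 2), bool))


class TestBookkeeping:
    def test_flagged_share_rounds_to_nearest_percent(self):
        assert outlier_percent(3045, 50760) == 6

    @given(st.integers(0, 1000), st.integers(1, 100000))
    @settings(max_examples=50, deadline=None)
    def test_percent_bounds(self, flagged, total):
        p = outlier_percent(flagged, flagged + total)
        assert 0 <= p <= 100
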
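"""Intensity, mean-shift, center-of-gravity, time-domain features and PCA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hdsemg import (build_feature_set, cog_feature, intensity_feature,
                    meanshift_features, pca_apply, pca_reduce, select_muscles,
                    td_features)
from hdsemg.features import dominant_mode


class TestIntensity:
    @pytest.mark.parametrize("value,expected", [(1.0, 0.0), (100.0, 2.0)])
    def test_uniform_region(self, value, expected):
        v = np.full((4, 4), value)
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        assert intensity_feature(v, mask) == pytest.approx(expected)

    def test_mixed_region_log_of_mean(self):
        v = np.zeros((1, 2))
        v[0] = [1.0, 10.0]
        mask = np.ones((1, 2), bool)
        assert intensity_feature(v, mask) == pytest.approx(np.log10(5.5))

    def test_permutation_invariant_and_monotone(self, rng):
        v = np.abs(rng.normal(size=(3, 5))) + 0.1
        mask = np.ones((3, 5), bool)
        base = intensity_feature(v, mask)
        perm = v.ravel()[rng.permutation(15)].reshape(3, 5)
        assert intensity_feature(perm, mask) == pytest.approx(base)
        assert intensity_feature(v + 0.5, mask) > base

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            intensity_feature(np.ones((2, 2)), np.zeros((2, 2), bool))


class TestCog:
    def test_symmetric_map_center(self):
        assert cog_feature(np.ones((5, 7))) == pytest.approx((3.0, 2.0))

    def test_single_pixel(self):
        v = np.zeros((4, 9))
        v[2, 7] = 3.0
        assert cog_feature(v) == (7.0, 2.0)

    def test_two_equal_pixels_midpoint(self):
        v = np.zeros((1, 11))
        v[0, 0] = v[0, 10] = 1.0
        assert cog_feature(v) == (5.0, 0.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cog_feature(np.zeros((3, 3)))


class TestMeanShift:
    @staticmethod
    def _kde_argmax(v, bw=2.0, step=0.1):
        w = np.clip(v, 0, None).ravel()
        w = w / w.sum()
        rows, cols = np.indices(v.shape)
        pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
        xs = np.arange(0, v.shape[1] - 1 + 1e-9, step)
        ys = np.arange(0, v.shape[0] - 1 + 1e-9, step)
        X, Y = np.meshgrid(xs, ys)
        q = np.column_stack([X.ravel(), Y.ravel()])
        d2 = ((q[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        dens = (w[None, :] * np.exp(-d2 / (2 * bw * bw))).sum(1)
        return q[np.argmax(dens)]

    def test_gaussian_blob_mode_near_center(self, rng):
        rr, cc = np.indices((6, 16))
        v = np.exp(-((rr - 3.0) ** 2 + (cc - 5.0) ** 2) / 8.0)
        ms = meanshift_features(v, seed=0)
        mx, my = dominant_mode(ms)
        assert np.hypot(mx - 5.0, my - 3.0) < 0.5

    def test_dominant_mode_matches_kde_oracle(self, rng):
        for i in range(5):
            rr, cc = np.indices((6, 16))
            r0, c0 = rng.uniform(1, 4), rng.uniform(2, 13)
            v = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / 8.0) \
                + 0.05 * rng.random((6, 16))
            ms = meanshift_features(v, seed=i)
            mx, my = dominant_mode(ms)
            om = self._kde_argmax(v)
            assert np.hypot(mx - om[0], my - om[1]) <= 0.5

    def test_two_equal_blobs_give_two_symmetric_modes(self):
        rr, cc = np.indices((8, 20))
        v = (np.exp(-((rr - 4.0) ** 2 + (cc - 3.0) ** 2) / 2.0)
             + np.exp(-((rr - 4.0) ** 2 + (cc - 16.0) ** 2) / 2.0))
        ms = meanshift_features(v, bandwidth=1.5, n_modes=2, seed=1)
        assert ms[2] > 0 and ms[5] > 0  # two real modes
        assert abs(ms[2] - ms[5]) / ms[2] < 0.05
        cols = sorted([ms[0], ms[3]])
        assert abs(cols[0] - 3.0) < 0.5 and abs(cols[1] - 16.0) < 0.5

    def test_deterministic_given_seed(self, rng):
        v = np.abs(rng.normal(size=(6, 10)))
        assert np.array_equal(meanshift_features(v, seed=4),
                              meanshift_features(v, seed=4))

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            meanshift_features(np.empty((0, 0)))


class TestTimeDomain:
    def test_alternating_signal_hand_computed(self):
        x = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        out = td_features(x)[0]
        rms_v, mav, zc, wl, ssc = out
        assert (rms_v, mav, zc, wl, ssc) == (1.0, 1.0, 7.0, 14.0, 6.0)

    def test_monotone_ramp(self):
        out = td_features(np.arange(10.0))[0]
        assert out[2] == 0 and out[4] == 0 and out[3] == pytest.approx(9.0)

    def test_zero_signal(self):
        out = td_features(np.zeros(16))[0]
        assert out[0] == out[1] == out[3] == 0.0

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=5,
                    max_size=30))
    @settings(max_examples=40, deadline=None)
    def test_sign_symmetry_with_zero_deadband(self, xs):
        x = np.asarray(xs)
        assert np.allclose(td_features(x), td_features(-x))

    def test_deadband_suppresses_small_crossings(self):
        x = np.array([0.01, -0.01] * 10)
        assert td_features(x, deadband=0.1)[0][2] == 0

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            td_features(np.zeros(2))


class TestPca:
    def test_rank_one_data_keeps_one_component(self, rng):
        base = rng.normal(size=5)
        X = np.outer(rng.normal(size=40), base)
        model = pca_reduce(X)
        assert model.n_retained == 1

    def test_isotropic_gaussian_needs_all_components(self, rng):
        X = rng.normal(size=(5000, 3))
        model = pca_reduce(X)
        assert model.n_retained == 3

    def test_training_mean_maps_to_zero(self, rng):
        X = rng.normal(size=(30, 6)) + 5.0
        model = pca_reduce(X)
        assert np.allclose(pca_apply(model, X.mean(axis=0)), 0.0, atol=1e-9)

    def test_minimality_of_retained_prefix(self, rng):
        X = rng.normal(size=(200, 8)) * np.array([10, 5, 3, 1, 1, 1, 1, 1])
        model = pca_reduce(X, threshold=0.90)
        cum = np.cumsum(model.explained_variance_ratio)
        assert cum[model.n_retained - 1] > 0.90
        if model.n_retained > 1:
            assert cum[model.n_retained - 2] <= 0.90

    def test_single_vector_rejected(self):
        with pytest.raises(ValueError):
            pca_reduce(np.ones((1, 4)))


@pytest.fixture(scope="module")
def tiny_dataset():
    from hdsemg import SimulationConfig, make_dataset
    base = SimulationConfig(duration=4.0)
    return make_dataset(seed=77, tasks=("flexion", "pronation"),
                        efforts=(30,), base_config=base)


class TestBuildFeatureSet:
    def test_intensity_set_has_five_muscle_columns(self, tiny_dataset):
        fs = build_feature_set("I", tiny_dataset, seed=1)
        assert fs.X.shape[1] == 5
        assert sorted(fs.muscle_cols) == sorted(
            ["brachioradialis", "anconeus", "pronator_teres", "biceps",
             "triceps"])

    def test_icg_set_length_is_five_plus_two_per_muscle(self, tiny_dataset):
        fs = build_feature_set("ICG", tiny_dataset, seed=1)
        assert fs.X.shape[1] == 5 + 2 * 5
        assert fs.pca_cols.size == 0

    def test_ims_meanshift_block_is_pca_designated(self, tiny_dataset):
        fs = build_feature_set("IMS", tiny_dataset, seed=1)
        assert fs.X.shape[1] == 5 + 3 * 9  # 5 I + 3 arrays x 3 modes x 3
        assert fs.pca_cols.size == 27

    def test_td_set_covers_all_channels(self, tiny_dataset):
        fs = build_feature_set("TD", tiny_dataset, seed=1)
        assert fs.X.shape[1] == 5 * (96 + 120 + 120)
        assert fs.pca_cols.size == fs.X.shape[1]

    def test_deterministic_given_seed(self, tiny_dataset):
        a = build_feature_set("I", tiny_dataset, seed=9)
        b = build_feature_set("I", tiny_dataset, seed=9)
        assert np.array_equal(a.X, b.X)

    def test_select_muscles_restricts_columns(self, tiny_dataset):
        fs = build_feature_set("ICG", tiny_dataset, seed=1)
        sub = select_muscles(fs, ["biceps", "triceps"])
        assert sub.X.shape[1] == 2 * 3  # I + (x, y) per muscle
        assert sorted(sub.muscle_cols) == ["biceps", "triceps"]

    def test_unknown_muscle_rejected(self, tiny_dataset):
        fs = build_feature_set("I", tiny_dataset, seed=1)
        with pytest.raises(ValueError, match="deltoid"):
            select_muscles(fs, ["deltoid"])

    def test_unknown_kind_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            build_feature_set("FD", tiny_dataset)
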
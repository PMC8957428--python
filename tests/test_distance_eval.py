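import numpy as np
import pytest

from hrvcdet import FeatureDataset, class_stats, feature_weights

from .oracles import oracle_class_stats, oracle_feature_weights

MODES = ["center_distance", "as_printed"]


def make_ds(groups):
    arrays = tuple(np.asarray(g, dtype=float) for g in groups)
    m = arrays[0].shape[1]
    return FeatureDataset(
        X=arrays,
        class_names=tuple(f"c{i}" for i in range(len(arrays))),
        feature_names=tuple(f"f{j}" for j in range(m)),
    )


def random_groups(rng, n_classes=3, n_per_class=6, n_features=3):
    return [rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), size=(n_per_class, n_features)).tolist() for _ in range(n_classes)]


class TestClassStats:
    def test_hand_example_mean_and_std(self):
        ds = make_ds([[[1.0], [2.0], [3.0]], [[4.0], [5.0], [6.0]]])
        st = class_stats(ds)
        assert st.u[0, 0] == pytest.approx(2.0)
        assert st.delta[0, 0] == pytest.approx(1.0)

    def test_hand_example_ordered_pair_distances(self):
        # {1,2,3}: ordered-pair distances 1,2,1,1,2,1 -> mean 8/6
        ds = make_ds([[[1.0], [2.0], [3.0]], [[4.0], [5.0], [6.0]]])
        st = class_stats(ds)
        assert st.d[0, 0] == pytest.approx(8.0 / 6.0, rel=1e-12)

    def test_constant_class_zero_spread(self):
        ds = make_ds([[[5.0], [5.0], [5.0], [5.0]], [[1.0], [2.0], [3.0]]])
        st = class_stats(ds)
        assert st.delta[0, 0] == st.d[0, 0] == st.tau[0, 0] == 0.0

    def test_class_with_single_sample_rejected(self):
        with pytest.raises(ValueError):
            make_ds([[[1.0]], [[2.0], [3.0]]])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            groups = random_groups(rng)
            st = class_stats(make_ds(groups))
            u, delta, d, tau = oracle_class_stats(groups)
            np.testing.assert_allclose(st.u, u, rtol=1e-9)
            np.testing.assert_allclose(st.delta, delta, rtol=1e-9)
            np.testing.assert_allclose(st.d, d, rtol=1e-9)
            np.testing.assert_allclose(st.tau, tau, rtol=1e-9)


class TestFeatureWeights:
    @pytest.mark.parametrize("mode", MODES)
    def test_matches_loop_oracle_on_random_datasets(self, mode):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n_classes = int(rng.integers(2, 5))
            n_per = int(rng.integers(3, 8))
            n_feat = int(rng.integers(1, 5))
            groups = random_groups(rng, n_classes, n_per, n_feat)
            w = feature_weights(make_ds(groups), mode=mode)
            eta, eta_norm = oracle_feature_weights(groups, mode=mode)
            np.testing.assert_allclose(w.eta, eta, rtol=1e-9)
            np.testing.assert_allclose(w.eta_norm, eta_norm, rtol=1e-9)

    def test_duplicated_feature_gets_equal_weight(self):
        rng = np.random.default_rng(2)
        col = [rng.normal(3 * y, 1, size=(6, 1)) for y in range(3)]
        groups = [np.hstack([c, c]) for c in col]
        w = feature_weights(make_ds(groups))
        assert w.eta[0] == pytest.approx(w.eta[1], rel=1e-12)
        assert w.eta_norm[0] == w.eta_norm[1] == 1.0

    @pytest.mark.parametrize("mode", MODES)
    def test_permutation_invariance(self, mode):
        rng = np.random.default_rng(13)
        groups = random_groups(rng)
        w0 = feature_weights(make_ds(groups), mode=mode)
        # permute samples within classes and reverse class order
        perm_groups = [np.asarray(g)[rng.permutation(len(g))] for g in groups][::-1]
        w1 = feature_weights(make_ds(perm_groups), mode=mode)
        np.testing.assert_allclose(w0.eta, w1.eta, rtol=1e-9)

    def test_scale_equivariance_leaves_eta_unchanged(self):
        rng = np.random.default_rng(17)
        groups = [np.asarray(g) for g in random_groups(rng)]
        w0 = feature_weights(make_ds(groups))
        c = 7.5
        scaled = [g * np.array([c, 1.0, 1.0]) for g in groups]
        w1 = feature_weights(make_ds(scaled))
        assert w1.clt_inner[0] == pytest.approx(c * w0.clt_inner[0], rel=1e-9)
        assert w1.clt_outer[0] == pytest.approx(c * w0.clt_outer[0], rel=1e-9)
        np.testing.assert_allclose(w1.f_inner, w0.f_inner, rtol=1e-9)
        np.testing.assert_allclose(w1.f_outer, w0.f_outer, rtol=1e-9)
        np.testing.assert_allclose(w1.eta, w0.eta, rtol=1e-9)

    def test_separated_feature_outranks_noise_feature(self):
        rng = np.random.default_rng(23)
        groups = []
        for y in range(2):
            a = rng.normal(10.0 * y, 1.0, size=(10, 1))  # separated
            b = rng.normal(0.0, 1.0, size=(10, 1))  # pure noise
            groups.append(np.hstack([a, b]))
        w = feature_weights(make_ds(groups))
        assert w.eta_norm[0] == 1.0
        assert w.eta_norm[0] > w.eta_norm[1]

    def test_monotone_in_class_mean_gap(self):
        ok = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            # center each class's noise so the class-mean gap is exactly the
            # nominal gap, not the gap plus a sampling offset
            noise = [
                (lambda g: g - g.mean(axis=0))(rng.normal(0, 1, size=(8, 2)))
                for _ in range(2)
            ]
            etas = []
            for gap in [0, 1, 2, 5, 10]:
                groups = [noise[y] + np.array([gap * y, 0.0]) for y in range(2)]
                etas.append(feature_weights(make_ds(groups)).eta_norm[0])
            if all(a <= b + 1e-12 for a, b in zip(etas, etas[1:])):
                ok += 1
        assert ok >= 0.95 * n_rep

    def test_informative_feature_recovery(self):
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(5000 + rep)
            groups = []
            for y in range(3):
                g = rng.normal(0, 1, size=(10, 10))
                g[:, 4] += 5.0 * y  # one mean-separated feature among 10
                groups.append(g)
            w = feature_weights(make_ds(groups))
            if w.eta_norm[4] == 1.0:
                hits += 1
        assert hits >= 95

    def test_all_zero_weights_warn(self):
        groups = [[[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]], [[1.0, 1.0], [1.0, 1.0]]]
        with pytest.warns(UserWarning, match="no discriminative"):
            w = feature_weights(make_ds(groups))
        assert np.all(w.eta_norm == 0.0)

    def test_unknown_mode_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            feature_weights(make_ds(random_groups(rng)), mode="mystery")
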
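"""Evaluation battery: receptive fields, geometry, stabilisation, decoding."""

import numpy as np
import pytest

import stec
from stec.evaluation import (
    block_entropy,
    confusion_from_responses,
    fit_gaussian_nb,
    gist_descriptor,
    nb_predict,
)


def zero_params(cfg):
    return stec.init_params(cfg, 0).zeros_like()


class TestReceptiveField:
    def test_zero_weight_model_flat_at_half(self, tiny_cfg):
        probes = stec.generate_rf_probes(100, shape=tiny_cfg.image_shape, subregion=(3, 3), seed=1)
        rf = stec.receptive_field(zero_params(tiny_cfg), probes)
        covered = rf["coverage"] > 0
        for h in (1, 2):
            np.testing.assert_allclose(rf["maps"][h][:, covered], 0.5)

    def test_uncovered_pixels_flagged_not_zero(self, tiny_cfg):
        # a single probe in the corner leaves most pixels uncovered
        probes = stec.StimulusSet(
            images=np.pad(np.ones((1, 3, 3)), ((0, 0), (0, 3), (0, 5))), labels=["probe"]
        )
        rf = stec.receptive_field(stec.init_params(tiny_cfg, 0), probes)
        assert np.isnan(rf["maps"][1][:, rf["coverage"] == 0]).all()
        assert not np.isnan(rf["maps"][1][:, rf["coverage"] > 0]).any()

    def test_masked_unit_map_is_baseline_outside_its_patch(self, tiny_cfg):
        """A unit driven only bottom-up from one patch shows structure only
        inside that patch's footprint; elsewhere the map equals the
        no-stimulus baseline sigma(0) = 0.5."""
        p = zero_params(tiny_cfg)
        rng = np.random.default_rng(2)
        mask = tiny_cfg.input_mask()
        p.bottom_up[1][:, 0] = mask[:, 0] * rng.uniform(0.5, 1.5, tiny_cfg.n_pixels)
        probes = stec.generate_rf_probes(400, shape=tiny_cfg.image_shape, subregion=(2, 2), seed=3)
        rf = stec.receptive_field(p, probes)
        footprint = mask[:, 0].reshape(tiny_cfg.image_shape)
        # probes whose block straddles the patch edge drive the unit while
        # also covering outside pixels; exclude those pixels from the
        # baseline comparison
        flat = probes.images.reshape(len(probes), -1) > 0.5
        touches = flat[:, mask[:, 0]].any(axis=1)
        contaminated = flat[touches].any(axis=0).reshape(tiny_cfg.image_shape)
        outside = ~footprint & ~contaminated & (rf["coverage"] > 0)
        assert outside.any()
        np.testing.assert_allclose(rf["maps"][1][0][outside], 0.5)
        assert (rf["maps"][1][0][footprint & (rf["coverage"] > 0)] > 0.5).any()

    def test_monte_carlo_stability_under_more_probes(self, tiny_cfg):
        p = stec.init_params(tiny_cfg, 4)
        a = stec.receptive_field(
            p, stec.generate_rf_probes(600, shape=tiny_cfg.image_shape, subregion=(3, 3), seed=5)
        )
        b = stec.receptive_field(
            p, stec.generate_rf_probes(1200, shape=tiny_cfg.image_shape, subregion=(3, 3), seed=6)
        )
        diff = np.nanmax(np.abs(a["maps"][1] - b["maps"][1]))
        assert diff < 0.05


class TestGlobalFeatureDistance:
    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 1, (32, 48))
        b = rng.uniform(0, 1, (32, 48))
        assert stec.global_feature_distance(a, a) == 0.0
        assert stec.global_feature_distance(a, b) == pytest.approx(
            stec.global_feature_distance(b, a)
        )
        assert stec.global_feature_distance(a, b) > 0

    def test_matches_descriptor_arithmetic(self):
        """Uniform field vs a single-orientation grating, against the
        descriptor pipeline evaluated explicitly."""
        ii = np.arange(32)[:, None] * np.ones((1, 48))
        grating = 0.5 + 0.5 * np.sin(2 * np.pi * ii / 8)
        flat = np.full((32, 48), 0.5)
        d = stec.global_feature_distance(grating, flat)
        expected = float(np.linalg.norm(gist_descriptor(grating) - gist_descriptor(flat)))
        assert d == pytest.approx(expected)
        assert d > 0.5  # grating has oriented energy the flat image lacks

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stec.global_feature_distance(np.zeros((4, 4)), np.zeros((5, 5)))


class TestLocalSimilarity:
    def test_perfect_monotone_case_gives_unit_correlation(self):
        z = np.linspace(0, 1, 50)
        d_s = np.abs(z[:, None] - z[None, :])
        responses = (2.0 * z + 0.3)[:, None]  # linear 1-D response code
        r = stec.local_similarity(None, responses, neighbour_fraction=0.2, image_distances=d_s)
        assert r == pytest.approx(1.0)

    def test_random_responses_decorrelated(self):
        rng = np.random.default_rng(8)
        z = rng.uniform(0, 1, 100)
        d_s = np.abs(z[:, None] - z[None, :])
        responses = rng.uniform(0, 1, (100, 8))
        r = stec.local_similarity(None, responses, neighbour_fraction=0.05, image_distances=d_s)
        assert abs(r) < 0.15

    def test_too_few_neighbours_rejected(self):
        d_s = np.abs(np.arange(10)[:, None] - np.arange(10)[None, :]).astype(float)
        with pytest.raises(ValueError):
            stec.local_similarity(None, np.zeros((10, 2)), 0.01, image_distances=d_s)


class TestDiscriminability:
    def test_identical_responses_give_zero(self):
        rng = np.random.default_rng(9)
        d_s = np.abs(rng.uniform(0, 1, 60)[:, None] - rng.uniform(0, 1, 60)[None, :])
        np.fill_diagonal(d_s, 0)
        responses = np.ones((60, 4))
        out = stec.discriminability(None, responses, image_distances=d_s)
        np.testing.assert_array_equal(out, 0.0)

    def test_monotone_response_distance_gives_one(self):
        """d_X strictly increasing in d_S: the two 99% sets coincide.
        Verified against a brute-force set computation."""
        z = np.sort(np.random.default_rng(10).uniform(0, 1, 200))
        d_s = np.abs(z[:, None] - z[None, :])
        responses = z[:, None]  # response distance == image distance
        out = stec.discriminability(None, responses, image_distances=d_s)
        # brute force for a few references
        for i in (0, 50, 150):
            ds = np.delete(d_s[i], i)
            th = np.percentile(ds, 99)
            den = {j for j in range(200) if j != i and d_s[i, j] > th}
            num = {j for j in den if abs(z[j] - z[i]) > th}
            assert len(num) / len(den) == 1.0
        np.testing.assert_array_equal(out, 1.0)

    def test_bounds_on_random_data(self):
        rng = np.random.default_rng(11)
        d_s = np.abs(rng.uniform(0, 1, (80, 80)))
        d_s = (d_s + d_s.T) / 2
        np.fill_diagonal(d_s, 0)
        out = stec.discriminability(None, rng.uniform(0, 1, (80, 5)), image_distances=d_s)
        assert ((out >= 0) & (out <= 1)).all()


class TestConfusionIndex:
    def test_zero_at_reference_time(self):
        rng = np.random.default_rng(12)
        f = rng.uniform(0, 1, (6, 10, 4))
        v = confusion_from_responses(f, np.roll(np.arange(6), 1), t_ref=10)
        np.testing.assert_allclose(v[:, 9], 0.0)

    def test_hand_set_vectors(self):
        f = np.zeros((2, 10, 2))
        f[0, :, :] = 0.2
        f[0, 9, :] = 0.4  # f_10(s)
        f[1, 9, :] = 0.6  # f_10(s')
        v = confusion_from_responses(f, np.array([1, 0]), t_ref=10)
        assert v[0, 0] == pytest.approx(1.0)  # sqrt(0.08)/sqrt(0.08)

    def test_zero_denominator_flagged_nan(self):
        f = np.zeros((2, 10, 3))
        v = confusion_from_responses(f, np.array([1, 0]), t_ref=10)
        assert np.isnan(v).all()


class TestNeuronalNoise:
    def test_spread_orders_entropy(self):
        rng = np.random.default_rng(13)
        tight = 0.5 + 0.01 * rng.standard_normal((5, 6))
        loose = 0.5 + 0.2 * rng.standard_normal((5, 6))
        assert block_entropy(loose, width=0.1) > block_entropy(tight, width=0.1)

    def test_gaussian_sigma_monotonicity(self):
        rng = np.random.default_rng(14)
        vals = []
        for sigma in (0.01, 0.05, 0.1):
            ent = np.mean(
                [block_entropy(0.5 + sigma * rng.standard_normal((5, 1)), 0.1) for _ in range(200)]
            )
            vals.append(ent)
        assert vals[0] < vals[1] < vals[2]

    def test_identical_blocks_identical_values(self, tiny_cfg):
        p = stec.init_params(tiny_cfg, 15)
        stim = stec.generate_naturalistic(6, shape=tiny_cfg.image_shape, seed=16)
        a = stec.neuronal_noise(p, stim, presentation_steps=10, block=5)
        b = stec.neuronal_noise(p, stim, presentation_steps=10, block=5)
        np.testing.assert_array_equal(a["entropy"], b["entropy"])

    def test_indivisible_block_rejected(self, tiny_cfg):
        p = stec.init_params(tiny_cfg, 15)
        stim = stec.generate_naturalistic(3, shape=tiny_cfg.image_shape, seed=16)
        with pytest.raises(ValueError):
            stec.neuronal_noise(p, stim, presentation_steps=12, block=5)


class TestDecoder:
    def test_separable_classes_decoded_perfectly(self):
        rng = np.random.default_rng(17)
        mu = np.linspace(0, 1, 10)[:, None] * np.ones((1, 4))
        train = mu[:, None, :] + 0.001 * rng.standard_normal((10, 3, 4))
        model = fit_gaussian_nb(train, var_floor=1e-6)
        test = mu + 0.001 * rng.standard_normal((10, 4))
        assert (nb_predict(model, test) == np.arange(10)).all()

    def test_label_permutation_collapses_accuracy(self):
        rng = np.random.default_rng(18)
        k = 40
        mu = rng.uniform(0, 1, (k, 6))
        train = mu[:, None, :] + 0.001 * rng.standard_normal((k, 2, 6))
        perm = np.roll(np.arange(k), 7)  # derangement of class assignments
        model = fit_gaussian_nb(train[perm], var_floor=1e-6)
        acc = np.mean(nb_predict(model, mu) == np.arange(k))
        assert acc <= 2.0 / k

    def test_agrees_with_sklearn_gaussian_nb(self):
        """Independent cross-check on well-separated data where the variance
        floor is immaterial."""
        from sklearn.naive_bayes import GaussianNB

        rng = np.random.default_rng(19)
        k, d = 8, 5
        mu = rng.uniform(0, 1, (k, d)) * 10
        train = mu[:, None, :] + 0.05 * rng.standard_normal((k, 20, d))
        x = train.reshape(-1, d)
        y = np.repeat(np.arange(k), 20)
        test = mu + 0.05 * rng.standard_normal((k, d))
        ours = nb_predict(fit_gaussian_nb(train, var_floor=1e-9), test)
        theirs = GaussianNB(var_smoothing=1e-12).fit(x, y).predict(test)
        np.testing.assert_array_equal(ours, theirs)

    def test_decode_over_time_outputs_bounded(self, tiny_cfg):
        p = stec.init_params(tiny_cfg, 20)
        stim = stec.generate_naturalistic(8, shape=tiny_cfg.image_shape, seed=21)
        dec = stec.decode_over_time(p, stim)
        assert dec["chance"] == pytest.approx(1 / 8)
        assert all(0.0 <= a <= 1.0 for a in dec["accuracy"].values())
        assert set(dec["accuracy"]) == set(range(1, 10))


class TestOrientationPreference:
    def test_hand_built_horizontal_gabor_prefers_horizontal(self):
        cfg = stec.HierarchyConfig(
            depth=2, units=(4, 4), image_shape=(16, 24), patch_shape=(16, 24), patch_count=1
        )
        p = zero_params(cfg)
        ii, jj = np.meshgrid(np.arange(16), np.arange(24), indexing="ij")
        gabor = np.cos(2 * np.pi * ii / 6) * np.exp(
            -(((ii - 8) / 4) ** 2 + ((jj - 12) / 6) ** 2) / 2
        )
        p.bottom_up[1][:, 0] = gabor.ravel() * 0.2
        op = stec.orientation_preference(p, bar_width=4)
        assert op[1]["preferred"][0] == 0.0

    def test_random_weight_null_shows_no_cardinal_bias(self):
        cfg = stec.HierarchyConfig(units=(8, 8), image_shape=(16, 24), patch_shape=(9, 15))
        fracs = [
            stec.orientation_preference(stec.init_params(cfg, seed), bar_width=4)[1][
                "cardinal_fraction"
            ]
            for seed in range(30)
        ]
        # 240 units at p = 2/8: mean within 3 binomial sigmas of 0.25
        assert abs(np.mean(fracs) - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 240)

    def test_histogram_counts_sum_to_units(self, tiny_cfg):
        op = stec.orientation_preference(stec.init_params(tiny_cfg, 22), bar_width=2)
        for h, units in ((1, tiny_cfg.units[0]), (2, tiny_cfg.units[1])):
            assert op[h]["histogram"].sum() == units


class TestSynapticStrength:
    def test_identity_zero_and_hand_columns(self):
        cfg = stec.HierarchyConfig(
            depth=2, units=(2, 2), image_shape=(2, 2), patch_shape=(2, 2), patch_count=1
        )
        p = zero_params(cfg)
        p.recurrent[1][:] = np.eye(2)
        p.recurrent[2][:] = np.array([[3.0, 0.0], [4.0, 0.0]])
        s = stec.synaptic_strength(p)
        np.testing.assert_allclose(s["recurrent_1"]["norms"], [1.0, 1.0])
        np.testing.assert_allclose(s["recurrent_2"]["norms"], [5.0, 0.0])
        np.testing.assert_allclose(s["top_down_1"]["norms"], [0.0, 0.0])


class TestResponseDistribution:
    def test_zero_weight_model_mass_at_half(self, tiny_cfg):
        stim = stec.generate_naturalistic(5, shape=tiny_cfg.image_shape, seed=23)
        rd = stec.response_distribution(zero_params(tiny_cfg), stim, bins=20)
        mid_bin = 10  # [0.5, 0.55) contains sigma(0) = 0.5
        assert rd["histograms"][:, :, mid_bin].min() == 1.0
        assert rd["middle_mass"] == 1.0

    def test_histograms_normalised(self, tiny_cfg):
        stim = stec.generate_naturalistic(5, shape=tiny_cfg.image_shape, seed=24)
        rd = stec.response_distribution(stec.init_params(tiny_cfg, 25), stim, bins=16)
        np.testing.assert_allclose(rd["histograms"].sum(axis=2), 1.0)
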
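import numpy as np
import pytest

from perfmosaic.attenuation import (AttenuationModel, GaussianComponent,
                                    classify_voxels, compartment_proportions,
                                    fit_three_component_model)
from perfmosaic.imaging import QCWarning
from perfmosaic.phantom import generate_chest_phantom

TRUE_W = (0.20, 0.60, 0.20)
TRUE_MU = (-900.0, -780.0, -620.0)
TRUE_SD = (30.0, 40.0, 50.0)


def draw_mixture(n, seed, w=TRUE_W, mu=TRUE_MU, sd=TRUE_SD):
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n, p=w)
    return rng.normal(np.asarray(mu)[comp], np.asarray(sd)[comp])


def make_model(weights=(1 / 3, 1 / 3, 1 / 3), means=TRUE_MU, sds=TRUE_SD):
    return AttenuationModel(components=tuple(
        GaussianComponent(w, m, s) for w, m, s in zip(weights, means, sds)))


class TestFit:
    def test_recovers_generating_parameters(self):
        x = draw_mixture(200_000, seed=0)
        m = fit_three_component_model(x, seed=0)
        assert np.allclose(m.weights, TRUE_W, atol=0.02)
        assert np.allclose(m.means, TRUE_MU, atol=5.0)
        assert np.all(np.abs(m.sds / np.array(TRUE_SD) - 1) < 0.10)
        assert m.fit_info["converged"]

    def test_constant_input_collapses_to_one_component(self):
        m = fit_three_component_model(np.full(5000, -800.0), seed=0)
        assert m.weights.max() >= 0.98
        assert m.means[np.argmax(m.weights)] == pytest.approx(-800.0, abs=0.5)

    def test_deterministic_for_fixed_seed(self):
        x = draw_mixture(50_000, seed=3)
        a = fit_three_component_model(x, seed=1)
        b = fit_three_component_model(x, seed=1)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.sds, b.sds)

    def test_permutation_stability(self):
        x = draw_mixture(50_000, seed=4)
        a = fit_three_component_model(x, seed=0)
        rng = np.random.default_rng(0)
        b = fit_three_component_model(rng.permutation(x), seed=0)
        assert np.allclose(a.weights, b.weights, atol=1e-6)
        assert np.allclose(a.means, b.means, atol=1e-6)

    def test_too_few_samples_hard_error(self):
        with pytest.raises(ValueError, match="at least 30"):
            fit_three_component_model(np.full(10, -800.0))

    def test_small_sample_warns(self):
        with pytest.warns(QCWarning, match="may be noisy"):
            fit_three_component_model(draw_mixture(1000, seed=0), seed=0)

    def test_weights_sum_to_one_and_ordered(self):
        m = fit_three_component_model(draw_mixture(50_000, seed=5), seed=0)
        assert abs(m.weights.sum() - 1.0) < 1e-9
        assert m.means[0] < m.means[1] < m.means[2]

    def test_mean_recovery_over_seeds(self):
        """Average absolute errors over several seeded draws stay small."""
        werr, muerr = [], []
        for s in range(5):
            x = draw_mixture(100_000, seed=s)
            m = fit_three_component_model(x, seed=s)
            werr.append(np.abs(m.weights - TRUE_W).mean())
            muerr.append(np.abs(m.means - TRUE_MU).mean())
        assert np.mean(werr) <= 0.02
        assert np.mean(muerr) <= 5.0


class TestClassify:
    def test_matches_direct_density_argmax(self, wellsep_phantom):
        spec, vol, seg, truth = wellsep_phantom
        model = make_model(weights=spec.weights, means=spec.means,
                           sds=spec.sds)
        mask = classify_voxels(vol, seg, model)
        sel = np.argwhere(mask.labels > 0)
        rng = np.random.default_rng(0)
        pick = sel[rng.choice(len(sel), size=1000, replace=False)]
        x = vol.data[tuple(pick.T)].astype(float)
        oracle = np.argmax(model.log_weighted_density(x), axis=1) + 1
        np.testing.assert_array_equal(mask.labels[tuple(pick.T)], oracle)

    def test_canonical_points(self):
        from perfmosaic.imaging import CTVolume
        from conftest import make_two_box_seg
        model = make_model()
        seg = make_two_box_seg()
        data = np.full((12, 12, 12), -800.0, dtype=np.float32)
        data[2, 3, 3] = -905.0
        data[2, 4, 4] = -780.0
        data[2, 5, 5] = -600.0
        vol = CTVolume(data=data, spacing=(1.0, 1.0, 1.0))
        mask = classify_voxels(vol, seg, model)
        assert mask.labels[2, 3, 3] == 1      # oligemic
        assert mask.labels[2, 4, 4] == 2      # normal
        assert mask.labels[2, 5, 5] == 3      # hyperemic
        assert mask.labels[0, 0, 0] == 0      # background

    def test_tie_goes_to_lower_mean(self):
        from perfmosaic.imaging import CTVolume
        from conftest import make_two_box_seg
        model = make_model(weights=(0.5, 0.5, 0.0),
                           means=(-800.0, -700.0, -600.0),
                           sds=(50.0, 50.0, 50.0))
        seg = make_two_box_seg()
        data = np.full((12, 12, 12), -750.0, dtype=np.float32)  # exact midpoint
        vol = CTVolume(data=data, spacing=(1.0, 1.0, 1.0))
        mask = classify_voxels(vol, seg, model)
        assert np.all(mask.labels[seg.lungs] == 1)

    def test_nonzero_exactly_on_in_scope_voxels(self, default_phantom):
        _, vol, seg, truth = default_phantom
        model = make_model()
        mask = classify_voxels(vol, seg, model, clip_range=(-1024.0, 100.0))
        in_scope = seg.lungs & (vol.data >= -1024.0) & (vol.data <= 100.0)
        np.testing.assert_array_equal(mask.labels > 0, in_scope)

    def test_ground_truth_agreement_wellseparated(self, wellsep_phantom):
        """MAP labels agree with phantom truth >= 97% at >= 4-SD separation."""
        spec, vol, seg, truth = wellsep_phantom
        from perfmosaic.imaging import extract_lung_samples
        left = extract_lung_samples(vol, seg, "left")
        right = extract_lung_samples(vol, seg, "right")
        model = fit_three_component_model(
            np.concatenate([left.values, right.values]), seed=0)
        mask = classify_voxels(vol, seg, model)
        sel = mask.labels > 0
        agree = np.mean(mask.labels[sel] == truth.labels[sel])
        assert agree >= 0.97


class TestProportions:
    def test_weights_identity(self):
        model = make_model(weights=(0.2, 0.6, 0.2))
        from perfmosaic.attenuation import CompartmentMask
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        labels[0] = 1; labels[1] = 2; labels[2] = 3
        w, c = compartment_proportions(model, CompartmentMask(labels=labels))
        assert (w.oligemic, w.normal, w.hyperemic) == pytest.approx((0.2, 0.6, 0.2))
        assert w.oligemic + w.normal + w.hyperemic == pytest.approx(1.0)
        assert (c.oligemic, c.normal, c.hyperemic) == pytest.approx(
            (1 / 3, 1 / 3, 1 / 3))

    def test_weight_vs_count_close_when_separated(self, wellsep_phantom):
        spec, vol, seg, truth = wellsep_phantom
        from perfmosaic.imaging import extract_lung_samples
        left = extract_lung_samples(vol, seg, "left")
        right = extract_lung_samples(vol, seg, "right")
        model = fit_three_component_model(
            np.concatenate([left.values, right.values]), seed=0)
        mask = classify_voxels(vol, seg, model)
        w, c = compartment_proportions(model, mask)
        for name in ("oligemic", "normal", "hyperemic"):
            assert abs(w.as_dict()[name] - c.as_dict()[name]) <= 0.01

    def test_degenerate_fit_dominant(self):
        m = fit_three_component_model(np.full(5000, -800.0), seed=0)
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        labels[:2] = 1 + int(np.argmax(m.weights))
        from perfmosaic.attenuation import CompartmentMask
        w, _ = compartment_proportions(m, CompartmentMask(labels=labels))
        assert max(w.as_dict().values()) >= 0.98
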
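"""Loss terms: closed forms, loop oracles, weight linearity."""

import numpy as np
import pytest

from fluorofill.autograd import Tensor
from fluorofill.losses import (LossWeights, TinyFeatureExtractor,
                               adversarial_loss, content_gan_objective,
                               edge_gan_objective, feature_matching_loss,
                               gram_matrix, l1_loss, perceptual_loss,
                               style_loss)


@pytest.fixture(scope="module")
def extractor():
    return TinyFeatureExtractor(seed=1234)


def bce_oracle(real: np.ndarray, fake: np.ndarray) -> float:
    eps = 1e-7
    total = 0.0
    for r in np.clip(real, eps, 1 - eps).ravel():
        total -= np.log(r) / real.size
    for f in np.clip(fake, eps, 1 - eps).ravel():
        total -= np.log(1 - f) / fake.size
    return total


class TestAdversarialLoss:
    def test_indifferent_discriminator_sits_at_entropy_floor(self):
        half = Tensor(np.full((2, 1, 4, 4), 0.5))
        loss = adversarial_loss(half, half, "discriminator")
        assert loss.item() == pytest.approx(2 * np.log(2), abs=1e-6)

    def test_generator_loss_vanishes_when_fooling(self):
        nearly_one = Tensor(np.full((1, 1, 4, 4), 1.0 - 1e-6))
        assert adversarial_loss(None, nearly_one, "generator").item() < 1e-4

    def test_random_scores_match_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        real = rng.uniform(0.05, 0.95, size=(2, 1, 8, 8))
        fake = rng.uniform(0.05, 0.95, size=(2, 1, 8, 8))
        loss = adversarial_loss(Tensor(real), Tensor(fake), "discriminator")
        assert loss.item() == pytest.approx(bce_oracle(real, fake), rel=1e-5)

    def test_out_of_range_scores_are_clamped(self):
        bad = Tensor(np.array([[-0.1, 1.2]]))
        loss = adversarial_loss(None, bad, "generator")
        assert np.isfinite(loss.item())


class TestFeatureMatching:
    def test_identical_features_give_zero(self):
        feats = [Tensor(np.random.default_rng(i).random((1, 4, 8, 8)))
                 for i in range(3)]
        assert feature_matching_loss(feats, feats).item() == 0.0

    def test_constant_offset_single_layer(self):
        a = Tensor(np.zeros((1, 2, 4, 4)))
        b = Tensor(np.full((1, 2, 4, 4), 0.5))
        assert feature_matching_loss([a], [b]).item() == pytest.approx(0.5)

    def test_matches_per_layer_oracle(self):
        rng = np.random.default_rng(1)
        real = [rng.normal(size=(2, c, 6, 6)) for c in (3, 5, 7)]
        fake = [rng.normal(size=r.shape) for r in real]
        expected = sum(np.abs(r - f).mean() for r, f in zip(real, fake))
        loss = feature_matching_loss([Tensor(r) for r in real],
                                     [Tensor(f) for f in fake])
        assert loss.item() == pytest.approx(expected, rel=1e-5)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            feature_matching_loss([Tensor(np.zeros((1, 2, 4, 4)))],
                                  [Tensor(np.zeros((1, 2, 5, 5)))])


class TestPixelAndPerceptual:
    def test_l1_closed_forms(self):
        a = Tensor(np.random.default_rng(0).random((1, 1, 8, 8)))
        assert l1_loss(a, a).item() == 0.0
        b = Tensor(a.data + 0.1)
        assert l1_loss(b, a).item() == pytest.approx(0.1, rel=1e-5)

    def test_l1_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((1, 1, 5, 5)), rng.random((1, 1, 5, 5))
        assert l1_loss(Tensor(a), Tensor(b)).item() == pytest.approx(
            float(np.abs(a - b).mean()), rel=1e-6)

    def test_perceptual_zero_on_identical(self, extractor):
        img = Tensor(np.random.default_rng(3).random((1, 1, 32, 32)))
        assert perceptual_loss(extractor, img, img).item() == 0.0

    def test_perceptual_matches_definitional_oracle(self, extractor):
        rng = np.random.default_rng(4)
        a = Tensor(rng.random((1, 1, 32, 32)))
        b = Tensor(np.clip(a.data + rng.normal(0, 0.1, a.shape), 0, 1))
        fa = [f.data for f in extractor(a)]
        fb = [f.data for f in extractor(b)]
        expected = sum(np.abs(x - y).mean() for x, y in zip(fa, fb))
        assert perceptual_loss(extractor, b, a).item() == pytest.approx(
            expected, rel=1e-4)

    def test_perceptual_grows_with_noise_amplitude(self, extractor):
        """More corruption never lowers the perceptual distance on average."""
        rng = np.random.default_rng(5)
        target = Tensor(rng.random((1, 1, 32, 32)))
        losses = []
        for amp in (0.02, 0.08, 0.25):
            vals = [perceptual_loss(
                extractor,
                Tensor(np.clip(target.data
                               + np.random.default_rng(s).normal(
                                   0, amp, target.shape), 0, 1)),
                target).item() for s in range(10)]
            losses.append(np.mean(vals))
        assert losses[0] < losses[1] < losses[2]


class TestStyleLoss:
    def test_zero_when_prediction_equals_reference(self, extractor):
        img = Tensor(np.random.default_rng(6).random((1, 1, 32, 32)))
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[8:16, 8:16] = 1
        assert style_loss(extractor, img, img, mask).item() == 0.0

    def test_gram_matrix_hand_computed(self):
        # two 2x2 channels: identity-patterned activation vs zeros
        phi = np.zeros((1, 2, 2, 2), dtype=np.float32)
        phi[0, 0] = np.eye(2)
        phi[0, 1] = np.eye(2)
        g = gram_matrix(Tensor(phi)).data[0]
        # G = F F^T / (C*H*W) with each flattened row (1,0,0,1): dot = 2
        np.testing.assert_allclose(g, np.full((2, 2), 2.0 / 8.0), atol=1e-6)

    def test_gram_difference_vs_zero_reference(self):
        phi = np.zeros((1, 2, 2, 2), dtype=np.float32)
        phi[0, 0] = np.eye(2)
        phi[0, 1] = np.eye(2)
        diff = (gram_matrix(Tensor(phi)).data
                - gram_matrix(Tensor(np.zeros_like(phi))).data)
        np.testing.assert_allclose(diff, gram_matrix(Tensor(phi)).data)

    def test_channel_permutation_changes_loss(self, extractor):
        rng = np.random.default_rng(7)
        a = rng.random((1, 1, 32, 32)).astype(np.float32)
        ga = gram_matrix(extractor(Tensor(a))[0])
        # permuting channels of the activation permutes the Gram rows/cols
        perm = np.random.default_rng(8).permutation(ga.shape[1])
        gp = ga.data[:, perm][:, :, perm]
        assert not np.allclose(gp, ga.data)


class TestCompositeObjectives:
    def test_edge_objective_weighted_sum_oracle(self):
        rng = np.random.default_rng(9)
        d_real = Tensor(rng.uniform(0.1, 0.9, (1, 1, 4, 4)))
        d_fake = Tensor(rng.uniform(0.1, 0.9, (1, 1, 4, 4)))
        feats_r = [Tensor(rng.normal(size=(1, 3, 4, 4)))]
        feats_f = [Tensor(rng.normal(size=(1, 3, 4, 4)))]
        w = LossWeights(lambda_adv1=1.0, lambda_fm=10.0)
        g, d = edge_gan_objective(d_real, d_fake, feats_r, feats_f, w)
        adv = adversarial_loss(None, d_fake, "generator").item()
        fm = feature_matching_loss(feats_r, feats_f).item()
        assert g.item() == pytest.approx(adv + 10.0 * fm, rel=1e-5)
        assert d.item() == pytest.approx(
            adversarial_loss(d_real, d_fake, "discriminator").item())

    def test_edge_objective_weight_isolation(self):
        rng = np.random.default_rng(10)
        d_fake = Tensor(rng.uniform(0.1, 0.9, (1, 1, 4, 4)))
        feats_r = [Tensor(rng.normal(size=(1, 3, 4, 4)))]
        feats_f = [Tensor(rng.normal(size=(1, 3, 4, 4)))]
        pure_fm = LossWeights(lambda_adv1=0.0, lambda_fm=1.0)
        g, _ = edge_gan_objective(Tensor(d_fake.data), d_fake,
                                  feats_r, feats_f, pure_fm)
        assert g.item() == pytest.approx(
            feature_matching_loss(feats_r, feats_f).item(), rel=1e-6)

    def test_content_objective_linear_in_each_weight(self, extractor):
        """Doubling one lambda doubles exactly that term's contribution."""
        rng = np.random.default_rng(11)
        pred = Tensor(rng.random((1, 1, 32, 32)))
        target = Tensor(rng.random((1, 1, 32, 32)))
        d_real = Tensor(rng.uniform(0.2, 0.8, (1, 1, 4, 4)))
        d_fake = Tensor(rng.uniform(0.2, 0.8, (1, 1, 4, 4)))
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[4:12, 4:12] = 1

        def total(**kw):
            w = LossWeights(**{**dict(lambda_l1=1.0, lambda_adv2=0.1,
                                      lambda_perc=0.1, lambda_style=250.0),
                               **kw})
            g, _ = content_gan_objective(pred, target, d_real, d_fake,
                                         extractor, mask, w)
            return g.item()

        base = total()
        for name in ("lambda_l1", "lambda_adv2", "lambda_perc",
                     "lambda_style"):
            default = getattr(LossWeights(), name)
            doubled = total(**{name: 2 * default})
            term = doubled - base          # finite difference = lambda*term
            zeroed = total(**{name: 0.0})
            assert base - zeroed == pytest.approx(term, rel=1e-3, abs=1e-7)

    def test_all_zero_weights_give_zero_generator_loss(self, extractor):
        pred = Tensor(np.random.default_rng(12).random((1, 1, 32, 32)))
        w = LossWeights(lambda_l1=0, lambda_adv2=0, lambda_perc=0,
                        lambda_style=0)
        g, _ = content_gan_objective(pred, pred,
                                     Tensor(np.full((1, 1, 2, 2), 0.5)),
                                     Tensor(np.full((1, 1, 2, 2), 0.5)),
                                     extractor, None, w)
        assert g.item() == 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_fm=-1.0)
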
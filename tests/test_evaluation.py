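"""Restoration metrics: PSNR/SSIM closed forms, Frechet distance, protocol."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from fluorofill.evaluation import (PSNR_CAP_DB, TinyEmbedder,
                                   evaluate_protocol, fid, frechet_distance,
                                   psnr, ssim)
from fluorofill.screening import GrayImage
from fluorofill.synthetic import SyntheticSceneSpec, generate_clean_image


def scenes(n, seed, size=64):
    return [generate_clean_image(SyntheticSceneSpec(image_size=size,
                                                    seed=seed + i))
            for i in range(n)]


class TestPsnr:
    def test_identical_images_hit_the_cap(self):
        a = np.random.default_rng(0).random((32, 32))
        assert psnr(a, a) == PSNR_CAP_DB

    def test_uniform_tenth_offset_is_twenty_db(self):
        a = np.full((32, 32), 0.4)
        assert psnr(a, a + 0.1) == pytest.approx(20.0, abs=1e-9)

    def test_full_range_error_is_zero_db(self):
        assert psnr(np.zeros((16, 16)), np.ones((16, 16))) == pytest.approx(0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert psnr(a, b) == pytest.approx(psnr(b, a))

    def test_noise_monotonically_degrades_psnr(self):
        rng = np.random.default_rng(2)
        base = rng.random((32, 32))
        values = []
        for amp in (0.01, 0.05, 0.2):
            trials = [psnr(base, np.clip(
                base + np.random.default_rng(s).normal(0, amp, base.shape),
                0, 1)) for s in range(10)]
            values.append(np.mean(trials))
        assert values[0] > values[1] > values[2]

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((8, 8)), np.zeros((9, 9)))


class TestSsim:
    def test_identical_images_score_one(self):
        a = np.random.default_rng(3).random((32, 32))
        assert ssim(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_reference_implementation(self):
        """Gaussian-window SSIM matches skimage at identical parameters."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.random((48, 48))
            b = np.clip(a + rng.normal(0, 0.15, a.shape), 0, 1)
            ref = structural_similarity(a, b, gaussian_weights=True,
                                        sigma=1.5,
                                        use_sample_covariance=False,
                                        data_range=1.0)
            assert ssim(a, b) == pytest.approx(ref, abs=1e-6)

    def test_inverted_image_stays_below_one(self):
        img = generate_clean_image(SyntheticSceneSpec(image_size=64, seed=0))
        value = ssim(img.data, 1.0 - img.data)
        assert value <= 1.0

    def test_symmetry_at_default_parameters(self):
        rng = np.random.default_rng(5)
        a, b = rng.random((32, 32)), rng.random((32, 32))
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_image_smaller_than_window_raises(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)))


class TestFrechetDistance:
    def test_identical_gaussians_give_zero(self):
        mu = np.array([1.0, -2.0])
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert frechet_distance(mu, cov, mu, cov) == pytest.approx(0.0,
                                                                   abs=1e-8)

    def test_identity_covariances_reduce_to_mean_shift(self):
        d = np.array([0.6, -0.8])   # ||d||^2 = 1.0
        eye = np.eye(2)
        assert frechet_distance(np.zeros(2), eye, d, eye) == pytest.approx(
            1.0, abs=1e-8)

    def test_commuting_diagonal_closed_form(self):
        # tr(S1+S2-2(S1 S2)^(1/2)) = 1+4+4+1 - 2*(2+2) = 2
        s1, s2 = np.diag([1.0, 4.0]), np.diag([4.0, 1.0])
        assert frechet_distance(np.zeros(2), s1, np.zeros(2),
                                s2) == pytest.approx(2.0, abs=1e-8)

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3)) + 1.0
        m1, c1 = a.mean(0), np.cov(a, rowvar=False)
        m2, c2 = b.mean(0), np.cov(b, rowvar=False)
        assert frechet_distance(m1, c1, m2, c2) == pytest.approx(
            frechet_distance(m2, c2, m1, c1), abs=1e-8)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            frechet_distance(np.zeros(2), np.eye(2), np.zeros(3), np.eye(3))


class TestFid:
    def test_set_against_itself_is_zero(self):
        imgs = scenes(30, seed=0, size=32)
        assert fid(imgs, imgs) == pytest.approx(0.0, abs=1e-6)

    def test_mean_shift_orders_fid(self):
        """Disjoint same-distribution samples score below shifted samples."""
        wins = 0
        embedder = TinyEmbedder()
        for seed in range(5):
            ref = scenes(60, seed=1000 * seed, size=32)
            same = scenes(60, seed=1000 * seed + 500, size=32)
            shifted = [GrayImage(np.clip(s.data * 0.6 + 0.35, 0, 1))
                       for s in same]
            if fid(ref, same, embedder) < fid(ref, shifted, embedder):
                wins += 1
        assert wins >= 4

    def test_nonnegative(self):
        a = scenes(10, seed=50, size=32)
        b = scenes(10, seed=90, size=32)
        assert fid(a, b) >= -1e-6

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            fid([], scenes(2, seed=0, size=32))


class TestEvaluateProtocol:
    def test_perfect_restoration_limits(self):
        originals = scenes(4, seed=10, size=48)
        masked = [GrayImage(np.clip(o.data + 0.2, 0, 1)) for o in originals]
        mask_rep, rest_rep = evaluate_protocol(originals, masked,
                                               list(originals))
        assert rest_rep.psnr_db == PSNR_CAP_DB
        assert rest_rep.ssim == pytest.approx(1.0, abs=1e-9)
        assert rest_rep.fid == pytest.approx(0.0, abs=1e-6)
        assert mask_rep.n_pairs == rest_rep.n_pairs == 4

    def test_identical_groups_report_identically(self):
        originals = scenes(3, seed=20, size=48)
        rep_a, rep_b = evaluate_protocol(originals, list(originals),
                                         list(originals))
        assert rep_a.psnr_db == rep_b.psnr_db
        assert rep_a.ssim == rep_b.ssim
        assert rep_a.fid == pytest.approx(rep_b.fid, abs=1e-9)

    def test_csv_emission(self, tmp_path):
        import pandas as pd

        originals = scenes(2, seed=30, size=48)
        out = tmp_path / "metrics.csv"
        evaluate_protocol(originals, list(originals), list(originals),
                          out_csv=out)
        table = pd.read_csv(out)
        assert list(table.group) == ["mask", "restoration"]

    def test_length_mismatch_raises(self):
        originals = scenes(2, seed=40, size=48)
        with pytest.raises(ValueError):
            evaluate_protocol(originals, originals[:1], originals)
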
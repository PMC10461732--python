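"""Quality metrics: closed-form PSNR/L1 checks, SSIM brute-force oracle."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from snapmosaic import (
    Hypercube,
    evaluate_suite,
    l1_error,
    perceptual_score,
    psnr,
    ssim,
)


class TestL1:
    def test_identical_is_zero(self):
        a = np.random.default_rng(0).random((8, 8))
        assert l1_error(a, a) == 0.0

    def test_constant_offset(self):
        a = np.random.default_rng(1).random((8, 8)) * 0.8
        a.flat[0] = 1.0  # reference max 1 -> normalisation is a no-op
        assert l1_error(a, a + 0.1) == pytest.approx(0.1, rel=1e-12)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((6, 7)), rng.random((6, 7))
        expected = np.mean(np.abs(a / a.max() - b / a.max()))
        assert l1_error(a, b) == pytest.approx(expected, rel=1e-12)


class TestPSNR:
    def test_closed_form_20db(self):
        a = np.full((10, 10), 0.5)
        a[0, 0] = 1.0
        b = a + 0.1
        assert psnr(a, b) == pytest.approx(20.0, abs=1e-10)

    def test_identical_gives_inf_sentinel(self):
        a = np.random.default_rng(3).random((5, 5))
        assert psnr(a, a) == np.inf

    def test_halving_error_adds_6db(self):
        rng = np.random.default_rng(4)
        ref = rng.random((16, 16))
        noise = rng.normal(0, 0.05, ref.shape)
        p1 = psnr(ref, ref + noise, normalise=False)
        p2 = psnr(ref, ref + noise / 2, normalise=False)
        assert p2 - p1 == pytest.approx(20 * np.log10(2), abs=1e-9)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        ref, test = rng.random(64), rng.random(64)
        perm = rng.permutation(64)
        assert psnr(ref, test, normalise=False) == pytest.approx(
            psnr(ref[perm], test[perm], normalise=False)
        )
        assert l1_error(ref, test, normalise=False) == pytest.approx(
            l1_error(ref[perm], test[perm], normalise=False)
        )


def _ssim_brute_force(ref, test):
    """Per-window gaussian-weighted SSIM over full 11x11 interior windows."""
    delta = np.zeros((11, 11))
    delta[5, 5] = 1.0
    kernel = gaussian_filter(delta, 1.5, truncate=3.5)
    kernel /= kernel.sum()
    c1, c2 = 0.01**2, 0.03**2
    vals = []
    h, w = ref.shape
    for cx in range(5, h - 5):
        for cy in range(5, w - 5):
            wx = ref[cx - 5 : cx + 6, cy - 5 : cy + 6]
            wy = test[cx - 5 : cx + 6, cy - 5 : cy + 6]
            ux = (kernel * wx).sum()
            uy = (kernel * wy).sum()
            vx = (kernel * wx * wx).sum() - ux * ux
            vy = (kernel * wy * wy).sum() - uy * uy
            cxy = (kernel * wx * wy).sum() - ux * uy
            vals.append(
                ((2 * ux * uy + c1) * (2 * cxy + c2))
                / ((ux * ux + uy * uy + c1) * (vx + vy + c2))
            )
    return float(np.mean(vals))


class TestSSIM:
    def test_identical_is_one(self):
        a = np.random.default_rng(6).random((16, 16))
        assert ssim(a, a) == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        ref = rng.random((16, 16))
        test = np.clip(ref + rng.normal(0, 0.1, ref.shape), 0, None)
        expected = _ssim_brute_force(ref / ref.max(), test / ref.max())
        assert ssim(ref, test) == pytest.approx(expected, abs=1e-8)

    def test_constant_images_luminance_only(self):
        # flat images: structure/contrast terms cancel, leaving the
        # closed-form luminance comparison (2ab + C1) / (a^2 + b^2 + C1)
        a, b = 0.8, 0.6
        c1 = 0.01**2
        expected = (2 * a * b + c1) / (a * a + b * b + c1)
        got = ssim(np.full((16, 16), a), np.full((16, 16), b), normalise=False)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_not_permutation_invariant(self):
        rng = np.random.default_rng(8)
        ref = rng.random((16, 16))
        test = np.clip(ref + rng.normal(0, 0.2, ref.shape), 0, 1)
        s0 = ssim(ref, test, normalise=False)
        perm = rng.permutation(256)
        s1 = ssim(ref.ravel()[perm].reshape(16, 16),
                  test.ravel()[perm].reshape(16, 16), normalise=False)
        assert abs(s0 - s1) > 1e-6

    def test_multiband_is_band_mean(self):
        rng = np.random.default_rng(9)
        ref = rng.random((16, 16, 3))
        test = np.clip(ref + rng.normal(0, 0.1, ref.shape), 0, None)
        per_band = [
            ssim(ref[:, :, b] / ref.max(), test[:, :, b] / ref.max(),
                 normalise=False)
            for b in range(3)
        ]
        assert ssim(ref, test) == pytest.approx(np.mean(per_band), rel=1e-12)


class TestPerceptual:
    def test_identical_is_zero(self):
        img = np.random.default_rng(10).random((16, 16, 3))
        assert perceptual_score(img, img) == 0.0

    def test_symmetric(self):
        rng = np.random.default_rng(11)
        a, b = rng.random((16, 16, 3)), rng.random((16, 16, 3))
        assert perceptual_score(a, b) == pytest.approx(perceptual_score(b, a))

    def test_monotone_along_blend_path(self):
        rng = np.random.default_rng(12)
        ref, far = rng.random((16, 16, 3)), rng.random((16, 16, 3))
        scores = [
            perceptual_score(ref, (1 - t) * ref + t * far)
            for t in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_custom_extractor_injectable(self):
        rng = np.random.default_rng(13)
        a, b = rng.random((8, 8, 3)), rng.random((8, 8, 3))
        flat = lambda img: np.asarray(img).ravel()
        expected = np.sqrt(np.mean((flat(a) - flat(b)) ** 2))
        assert perceptual_score(a, b, extractor=flat) == pytest.approx(expected)


class TestEvaluateSuite:
    def _pairs(self):
        rng = np.random.default_rng(14)
        wl = np.linspace(460, 630, 13)
        pairs = []
        for _ in range(3):
            ref = Hypercube(0.2 + 0.6 * rng.random((16, 16, 13)), wl, "ideal")
            rec = Hypercube(
                np.clip(ref.data + rng.normal(0, 0.02, ref.shape), 0, None),
                wl, "ideal",
            )
            pairs.append((ref, rec))
        return pairs

    def test_identical_pair_scores(self):
        (ref, _), *_ = self._pairs()
        report = evaluate_suite([(ref, ref)])
        row = report["per_image"][0]
        assert row["cube_l1"] == 0.0
        assert row["cube_ssim"] == 1.0
        assert row["cube_psnr_db"] == np.inf
        assert row["rgb_perceptual"] == 0.0

    def test_summary_matches_hand_average(self, tmp_path):
        pairs = self._pairs()
        report = evaluate_suite(
            pairs, out_csv=tmp_path / "r.csv", out_json=tmp_path / "r.json"
        )
        vals = [r["cube_psnr_db"] for r in report["per_image"]]
        assert report["summary"]["cube_psnr_db"]["mean"] == pytest.approx(
            np.mean(vals)
        )
        assert (tmp_path / "r.csv").exists() and (tmp_path / "r.json").exists()

    def test_report_schema_stable(self):
        pairs = self._pairs()
        a = evaluate_suite(pairs)
        b = evaluate_suite(pairs)
        assert a == b
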
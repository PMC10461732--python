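"""Full-reference quality metrics for reconstructed hypercubes and sRGB images.

Average L1 error, PSNR and SSIM, plus a pluggable learned-perceptual score.
Cube metrics normalise both inputs by the *reference* cube's maximum, so PSNR
(range-dependent) is comparable across scenes; SSIM uses the Wang et al.
defaults (gaussian 11x11 window, sigma 1.5, K1=0.01, K2=0.03, dynamic range
1.0) applied per band and averaged.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from skimage.metrics import structural_similarity

from .colour import ColourimetrySpec, hypercube_to_srgb
from .mosaic import Hypercube

__all__ = [
    "l1_error",
    "psnr",
    "ssim",
    "perceptual_score",
    "GradientFeatureExtractor",
    "evaluate_suite",
]

PSNR_IDENTICAL = np.inf  # sentinel for zero-MSE pairs


def _as_array(a) -> np.ndarray:
    return a.data if isinstance(a, Hypercube) else np.asarray(a, dtype=np.float64)


def _normalised_pair(ref, test):
    ref = _as_array(ref)
    test = _as_array(test)
    if ref.shape != test.shape:
        raise ValueError("metric inputs must have equal shapes")
    peak = ref.max()
    if peak <= 0:
        return ref.astype(np.float64), test.astype(np.float64)
    return ref / peak, test / peak


def l1_error(ref, test, normalise: bool = True) -> float:
    """Mean absolute difference (after reference-max normalisation)."""
    if normalise:
        ref, test = _normalised_pair(ref, test)
    else:
        ref, test = _as_array(ref), _as_array(test)
    return float(np.mean(np.abs(ref - test)))


def psnr(ref, test, normalise: bool = True) -> float:
    """Peak signal-to-noise ratio in dB with peak 1.0.

    ``10 * log10(1 / MSE)``; identical inputs return the ``inf`` sentinel.
    """
    if normalise:
        ref, test = _normalised_pair(ref, test)
    else:
        ref, test = _as_array(ref), _as_array(test)
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return PSNR_IDENTICAL
    return 10.0 * np.log10(1.0 / mse)


def ssim(ref, test, normalise: bool = True) -> float:
    """Structural similarity; multi-band inputs are averaged over bands."""
    if normalise:
        ref, test = _normalised_pair(ref, test)
    else:
        ref, test = _as_array(ref), _as_array(test)
    if ref.ndim == 2:
        ref = ref[:, :, None]
        test = test[:, :, None]
    vals = [
        structural_similarity(
            ref[:, :, b],
            test[:, :, b],
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=1.0,
        )
        for b in range(ref.shape[2])
    ]
    return float(np.mean(vals))


class GradientFeatureExtractor:
    """Deterministic multi-scale feature map for the perceptual score.

    A synthetic stand-in for a learned feature network: per-channel image
    gradients and local means over an octave pyramid.  It has no trained
    weights, is symmetric in use and linear in the image, which makes the
    perceptual score a well-behaved feature-space metric (zero iff the
    images agree, monotone along linear blends toward the reference).
    """

    def __init__(self, levels: int = 3):
        self.levels = levels

    def __call__(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        if img.dtype == np.uint8 or img.max() > 1.0 + 1e-9:
            img = img / 255.0
        if img.ndim == 2:
            img = img[:, :, None]
        feats = []
        cur = img
        for _ in range(self.levels):
            gx = np.diff(cur, axis=0, prepend=cur[:1])
            gy = np.diff(cur, axis=1, prepend=cur[:, :1])
            feats.extend([cur.ravel(), gx.ravel(), gy.ravel()])
            if min(cur.shape[0], cur.shape[1]) < 2:
                break
            h, w = cur.shape[0] // 2 * 2, cur.shape[1] // 2 * 2
            cur = cur[:h, :w].reshape(h // 2, 2, w // 2, 2, -1).mean(axis=(1, 3))
        return np.concatenate(feats)


def perceptual_score(ref_rgb, test_rgb, extractor=None) -> float:
    """Feature-space RMS distance between two RGB images; 0 iff identical."""
    if extractor is None:
        extractor = GradientFeatureExtractor()
    fr = extractor(np.asarray(ref_rgb))
    ft = extractor(np.asarray(test_rgb))
    if fr.shape != ft.shape:
        raise ValueError("images must have equal shapes")
    return float(np.sqrt(np.mean((fr - ft) ** 2)))


def evaluate_suite(
    pairs,
    colour_spec: ColourimetrySpec | None = None,
    extractor=None,
    out_csv=None,
    out_json=None,
) -> dict:
    """Score (reference ideal cube, reconstruction) pairs.

    Computes L1/SSIM/PSNR on the cubes and on their sRGB renderings, plus
    the perceptual score on sRGB; returns per-image rows and mean/std
    summaries, optionally written as CSV with a JSON sidecar.
    """
    colour_spec = ColourimetrySpec.d65_2deg() if colour_spec is None else colour_spec
    rows = []
    for idx, (ref, rec) in enumerate(pairs):
        ref_rgb = hypercube_to_srgb(ref, spec=colour_spec, as_uint8=False)
        rec_rgb = hypercube_to_srgb(rec, spec=colour_spec, as_uint8=False)
        rows.append(
            {
                "image": idx,
                "cube_l1": l1_error(ref, rec),
                "cube_ssim": ssim(ref, rec),
                "cube_psnr_db": psnr(ref, rec),
                "rgb_l1": l1_error(ref_rgb, rec_rgb, normalise=False),
                "rgb_ssim": ssim(ref_rgb, rec_rgb, normalise=False),
                "rgb_psnr_db": psnr(ref_rgb, rec_rgb, normalise=False),
                "rgb_perceptual": perceptual_score(ref_rgb, rec_rgb, extractor),
            }
        )
    metrics = [k for k in rows[0] if k != "image"] if rows else []
    summary = {}
    for m in metrics:
        vals = [r[m] for r in rows]
        finite = [v for v in vals if np.isfinite(v)]
        summary[m] = {
            "mean": float(np.mean(finite)) if finite else float("inf"),
            "std": float(np.std(finite)) if finite else 0.0,
            "n_infinite": len(vals) - len(finite),
        }
    report = {"per_image": rows, "summary": summary}
    if out_csv is not None:
        with open(out_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["image"] + metrics)
            writer.writeheader()
            writer.writerows(rows)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(report, indent=2, default=str))
    return report
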
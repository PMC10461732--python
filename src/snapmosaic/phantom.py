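"""Synthetic tissue-like reflectance phantoms.

Generates high-spectral-resolution hypercubes that mimic the statistical
structure of white-balanced surgical reflectance data: a small set of
materials with smooth visible/NIR spectra (sums of a few Gaussian lobes on a
gentle baseline), mixed spatially through smooth abundance maps derived from
blurred Voronoi regions, with dark curvilinear vessel-like strokes
multiplying an absorption profile on top.  Vessels supply the
high-frequency structure on which learned demosaicking separates itself
from bilinear interpolation.

Everything is reproducible bit-for-bit from (spec, seed), and datasets are
described by a manifest recording every per-image seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .mosaic import Hypercube, simulate_pair
from .sensor import SensorModel

__all__ = [
    "PhantomSpec",
    "sample_material_spectra",
    "make_phantom_hypercube",
    "make_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom family.

    Defaults emulate a desk-scale stand-in for line-scan surgical cubes:
    64 x 64 pixels, 160 bands spanning 400-1000 nm, four materials, and a
    dense vessel network (intraoperative brain-surface scenes are heavily
    vascularised; the strokes carry the high-frequency spatial structure
    that separates demosaicking methods).
    """

    shape: tuple = (64, 64)
    n_bands: int = 160
    wavelength_range: tuple = (400.0, 1000.0)
    n_materials: int = 4
    n_vessels: int = 8
    vessel_width: float = 1.5
    region_smoothness: float = 6.0
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_materials < 1:
            raise ValueError("need at least one material")
        if self.n_bands < 2 or min(self.shape) < 1:
            raise ValueError("degenerate phantom dimensions")
        if self.noise_level < 0 or self.n_vessels < 0:
            raise ValueError("noise_level and n_vessels must be non-negative")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.n_bands)


def sample_material_spectra(spec: PhantomSpec, rng=None) -> np.ndarray:
    """Draw one smooth reflectance spectrum per material.

    Each spectrum is a slowly varying baseline plus 2-4 Gaussian lobes in
    wavelength, clipped-free by construction to [0.05, 0.95]; materials are
    redrawn until pairwise L2 distances exceed a separation floor.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    wl = spec.wavelengths
    lo, hi = spec.wavelength_range
    span = hi - lo
    spectra = []
    floor = 0.08 * np.sqrt(spec.n_bands)
    guard = 0
    while len(spectra) < spec.n_materials:
        base = 0.2 + 0.3 * rng.random()
        slope = rng.uniform(-0.15, 0.25) * (wl - lo) / span
        s = base + slope
        for _ in range(rng.integers(2, 5)):
            centre = rng.uniform(lo, hi)
            width = rng.uniform(0.05, 0.25) * span
            amp = rng.uniform(-0.2, 0.3)
            s = s + amp * np.exp(-0.5 * ((wl - centre) / width) ** 2)
        s = 0.05 + 0.9 * (s - s.min()) / max(s.max() - s.min(), 1e-9)
        if all(np.linalg.norm(s - t) >= floor for t in spectra) or guard > 200:
            spectra.append(s)
        guard += 1
    return np.stack(spectra)


def _abundance_maps(spec: PhantomSpec, rng) -> np.ndarray:
    """Smooth per-material abundance maps that sum to one at every pixel."""
    x, y = spec.shape
    if spec.n_materials == 1:
        return np.ones((x, y, 1))
    seeds = rng.uniform(0, 1, size=(spec.n_materials, 2)) * [x, y]
    gx, gy = np.meshgrid(np.arange(x), np.arange(y), indexing="ij")
    d2 = (gx[None] - seeds[:, 0, None, None]) ** 2 + (
        gy[None] - seeds[:, 1, None, None]
    ) ** 2
    labels = np.argmin(d2, axis=0)
    maps = np.stack(
        [
            gaussian_filter((labels == m).astype(np.float64), spec.region_smoothness)
            for m in range(spec.n_materials)
        ],
        axis=-1,
    )
    maps += 1e-6
    return maps / maps.sum(axis=2, keepdims=True)


def _vessel_mask(spec: PhantomSpec, rng) -> np.ndarray:
    """Attenuation map in (0, 1]: 1 away from vessels, darker on strokes."""
    x, y = spec.shape
    att = np.zeros((x, y))
    for _ in range(spec.n_vessels):
        t = np.linspace(0, 1, 4 * max(x, y))
        # smooth random parametric curve crossing the frame
        p0 = rng.uniform(0, 1, 2) * [x, y]
        p1 = rng.uniform(0, 1, 2) * [x, y]
        amp = rng.uniform(0.05, 0.25) * min(x, y)
        phase = rng.uniform(0, 2 * np.pi)
        normal = np.array([-(p1 - p0)[1], (p1 - p0)[0]])
        nrm = np.linalg.norm(normal)
        normal = normal / (nrm if nrm > 0 else 1.0)
        pts = (
            p0[None, :] * (1 - t)[:, None]
            + p1[None, :] * t[:, None]
            + amp * np.sin(2 * np.pi * t * rng.uniform(0.5, 1.5) + phase)[:, None]
            * normal[None, :]
        )
        ink = np.zeros((x, y))
        ij = np.round(pts).astype(int)
        keep = (ij[:, 0] >= 0) & (ij[:, 0] < x) & (ij[:, 1] >= 0) & (ij[:, 1] < y)
        ink[ij[keep, 0], ij[keep, 1]] = 1.0
        sigma = spec.vessel_width / 2.0 * rng.uniform(0.6, 1.6)
        att = np.maximum(att, gaussian_filter(ink, sigma))
    if att.max() > 0:
        att = att / att.max()
    return 1.0 - 0.7 * att


def _absorption_profile(wl: np.ndarray) -> np.ndarray:
    """Blood-like relative absorption: strong in the green, weak in the NIR."""
    lo, hi = wl[0], wl[-1]
    prof = 0.85 * np.exp(-0.5 * ((wl - 545.0) / 45.0) ** 2) + 0.15 * np.exp(
        -(wl - lo) / max(hi - lo, 1.0)
    )
    return np.clip(prof, 0.0, 1.0)


def make_phantom_hypercube(spec: PhantomSpec) -> Hypercube:
    """Generate one HR reflectance phantom.

    Per-pixel spectra are convex mixtures of the material spectra weighted
    by the abundance maps; vessel strokes attenuate multiplicatively with a
    wavelength-dependent absorption profile; optional white Gaussian noise
    is added and clipped at zero.
    """
    rng = np.random.default_rng(spec.seed)
    spectra = sample_material_spectra(spec, rng)
    maps = _abundance_maps(spec, rng)
    cube = maps @ spectra  # (X, Y, M) @ (M, B)
    if spec.n_vessels > 0:
        att = _vessel_mask(spec, rng)
        prof = _absorption_profile(spec.wavelengths)
        cube = cube * (1.0 - (1.0 - att)[:, :, None] * prof[None, None, :])
    if spec.noise_level > 0:
        cube = cube + rng.normal(0.0, spec.noise_level, cube.shape)
    cube = np.clip(cube, 0.0, None)
    return Hypercube(cube, spec.wavelengths, role="hr")


def make_dataset(
    spec: PhantomSpec,
    sensor: SensorModel,
    count: int,
    split: tuple = (0.6, 0.2, 0.2),
    manifest_path=None,
):
    """Generate ``count`` paired samples and split them train/val/test.

    Per-image seeds are derived from the spec seed; the manifest (JSON)
    records them so any split can be regenerated bit-identically.
    """
    if count < 1:
        raise ValueError("count must be positive")
    if len(split) != 3 or abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must be three values summing to 1")
    root = np.random.default_rng(spec.seed)
    image_seeds = [int(s) for s in root.integers(0, 2**31 - 1, size=count)]
    samples = []
    for s in image_seeds:
        hr = make_phantom_hypercube(replace(spec, seed=s))
        samples.append(simulate_pair(hr, sensor))
    n_train = int(round(split[0] * count))
    n_val = int(round(split[1] * count))
    n_val = min(n_val, count - n_train)
    splits = {
        "train": samples[:n_train],
        "val": samples[n_train : n_train + n_val],
        "test": samples[n_train + n_val :],
    }
    manifest = {
        "spec": {
            "shape": list(spec.shape),
            "n_bands": spec.n_bands,
            "wavelength_range": list(spec.wavelength_range),
            "n_materials": spec.n_materials,
            "n_vessels": spec.n_vessels,
            "vessel_width": spec.vessel_width,
            "region_smoothness": spec.region_smoothness,
            "noise_level": spec.noise_level,
            "seed": spec.seed,
        },
        "sensor": sensor.name,
        "count": count,
        "image_seeds": image_seeds,
        "split_sizes": {k: len(v) for k, v in splits.items()},
    }
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=2))
    return splits, manifest
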
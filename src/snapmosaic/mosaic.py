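"""Forward model: from a high-spectral-resolution cube to a snapshot mosaic.

Simulates what an ``n x n`` snapshot-mosaic sensor would have recorded when
pointed at the scene captured by a slow line-scan camera:

1. white-balance the raw cube against white/dark references (flat-field
   correction) to obtain reflectance,
2. apply the sensor's measured spectral responses band by band (an inner
   product of each response curve with the per-pixel spectrum, trapezoidal
   quadrature) giving the *intermediate* cube (X x Y x ns),
3. spatially subsample the intermediate cube through the mosaic pattern,
   keeping one band per pixel, giving the scalar snapshot image (X x Y),
4. apply the *ideal* Lorentzian responses to the same input, giving the
   *ideal* target cube (X x Y x ni) that demosaicking aims to recover.

The (snapshot, intermediate, ideal) triplet is the paired sample used for
supervised training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .sensor import (
    MosaicPattern,
    SensorModel,
    SpectralResponseMatrix,
    WavelengthGrid,
)

__all__ = [
    "Hypercube",
    "SnapshotMosaic",
    "PairedSample",
    "white_balance",
    "apply_spectral_response",
    "mosaic_subsample",
    "scatter_to_cube",
    "make_ideal_hypercube",
    "simulate_pair",
]


@dataclass(frozen=True)
class Hypercube:
    """Rank-3 hyperspectral datum: X rows x Y cols x B bands, plus the band
    centre wavelengths (nm).  ``role`` tags where the cube sits in the
    pipeline: ``"hr"`` (high spectral resolution input), ``"intermediate"``
    (sensor-response bands, ns) or ``"ideal"`` (Lorentzian target bands, ni).
    """

    data: np.ndarray
    band_centers: np.ndarray
    role: str = "hr"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        centers = np.asarray(self.band_centers, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError("hypercube data must be rank-3 (X, Y, bands)")
        if centers.ndim != 1 or centers.size != data.shape[2]:
            raise ValueError("band_centers length must equal the band axis")
        if not np.all(np.isfinite(data)):
            raise ValueError("hypercube data must be finite")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "band_centers", centers)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class SnapshotMosaic:
    """Scalar snapshot image (X x Y) with the mosaic pattern that produced it.

    Frame dimensions need not be multiples of the block size; partial edge
    blocks are kept, as on real sensors.
    """

    image: np.ndarray
    pattern: MosaicPattern

    def __post_init__(self) -> None:
        image = np.asarray(self.image)
        if image.ndim != 2:
            raise ValueError("snapshot image must be 2-D")
        if not np.all(np.isfinite(image)):
            raise ValueError("snapshot image must be finite")
        object.__setattr__(self, "image", image)

    @property
    def shape(self) -> tuple:
        return self.image.shape

    def band_map(self) -> np.ndarray:
        """Band index sampled at each pixel (X x Y integer map)."""
        x, y = self.image.shape
        n = self.pattern.n
        rows = np.arange(x) % n
        cols = np.arange(y) % n
        return self.pattern.assignment[np.ix_(rows, cols)]


@dataclass(frozen=True)
class PairedSample:
    """Supervised training triplet: snapshot + intermediate + ideal cubes."""

    snapshot: SnapshotMosaic
    intermediate: Hypercube
    ideal: Hypercube

    def __post_init__(self) -> None:
        s = self.snapshot.image.shape
        if self.intermediate.shape[:2] != s or self.ideal.shape[:2] != s:
            raise ValueError("paired sample members must share spatial dims")


def white_balance(raw, white, dark=None):
    """Flat-field correction: ``(raw - dark) / (white - dark)``, clipped at 0.

    ``white`` and ``dark`` may be full cubes or per-band vectors (broadcast
    over the spatial axes).  ``dark`` defaults to zero.
    """
    raw_data = raw.data if isinstance(raw, Hypercube) else np.asarray(raw)
    w = white.data if isinstance(white, Hypercube) else np.asarray(white)
    d = (
        np.zeros(())
        if dark is None
        else (dark.data if isinstance(dark, Hypercube) else np.asarray(dark))
    )
    denom = w - d
    if np.any(denom <= 0):
        raise ValueError("degenerate reference: white must exceed dark everywhere")
    out = np.clip((raw_data - d) / denom, 0.0, None)
    if isinstance(raw, Hypercube):
        return Hypercube(out, raw.band_centers, raw.role)
    return out


def _resample_to_grid(hr: Hypercube, grid: WavelengthGrid) -> np.ndarray:
    """Cubic interpolation of each pixel spectrum onto the sensor grid.

    Grid wavelengths outside the cube's band range contribute zero (no
    spectral extrapolation).
    """
    centers = hr.band_centers
    if centers.size == len(grid) and np.allclose(centers, grid.values):
        return np.asarray(hr.data, dtype=np.float64)
    if not np.all(np.diff(centers) > 0):
        order = np.argsort(centers)
        centers = centers[order]
        hr = Hypercube(hr.data[:, :, order], centers, hr.role)
    spline = CubicSpline(centers, hr.data, axis=2, extrapolate=False)
    out = spline(grid.values)
    return np.nan_to_num(out, nan=0.0)


def apply_spectral_response(
    hr: Hypercube, responses: SpectralResponseMatrix, grid: WavelengthGrid | None = None
) -> Hypercube:
    """Project per-pixel spectra through the sensor's band responses.

    Output band ``b`` at pixel ``p`` is the quadrature inner product
    ``sum_l responses[b, l] * spectrum_p(l) * w(l)`` with trapezoidal
    weights ``w`` from the wavelength grid, so values are stable under grid
    densification.  Spectra are resampled to the grid if the cube's band
    centres differ from it.
    """
    grid = responses.grid if grid is None else grid
    if len(grid) != len(responses.grid) or not np.allclose(
        grid.values, responses.grid.values
    ):
        raise ValueError("responses and grid must agree")
    spectra = _resample_to_grid(hr, grid)
    kernel = responses.responses * grid.weights  # (nb, nd)
    out = spectra @ kernel.T
    return Hypercube(out, responses.band_centers(), role="intermediate")


def mosaic_subsample(intermediate: Hypercube, pattern: MosaicPattern) -> SnapshotMosaic:
    """Keep one band per pixel according to the mosaic pattern.

    ``image[x, y] = intermediate[x, y, assignment[x mod n, y mod n]]``.
    """
    if intermediate.n_bands != pattern.n_bands:
        raise ValueError(
            f"cube has {intermediate.n_bands} bands but the pattern samples "
            f"{pattern.n_bands}"
        )
    if pattern.assignment.max() >= intermediate.n_bands:
        raise ValueError("pattern band index out of range")
    x, y, _ = intermediate.shape
    n = pattern.n
    band = pattern.assignment[np.ix_(np.arange(x) % n, np.arange(y) % n)]
    image = np.take_along_axis(intermediate.data, band[:, :, None], axis=2)[:, :, 0]
    return SnapshotMosaic(image, pattern)


def scatter_to_cube(snapshot: SnapshotMosaic, n_bands: int | None = None) -> np.ndarray:
    """Place each snapshot pixel back at its (pixel, band) slot in a zero cube.

    Inverse direction of :func:`mosaic_subsample` on the sampled lattice:
    re-subsampling the scattered cube recovers the snapshot exactly.
    """
    if n_bands is None:
        n_bands = snapshot.pattern.n_bands
    x, y = snapshot.image.shape
    cube = np.zeros((x, y, n_bands), dtype=snapshot.image.dtype)
    band = snapshot.band_map()
    np.put_along_axis(cube, band[:, :, None], snapshot.image[:, :, None], axis=2)
    return cube


def make_ideal_hypercube(
    hr: Hypercube,
    ideal_responses: SpectralResponseMatrix,
    grid: WavelengthGrid | None = None,
) -> Hypercube:
    """Target cube for demosaicking: the input seen through ideal Lorentzian
    bands (ni <= ns of them)."""
    cube = apply_spectral_response(hr, ideal_responses, grid)
    return Hypercube(cube.data, cube.band_centers, role="ideal")


def simulate_pair(hr: Hypercube, sensor: SensorModel) -> PairedSample:
    """Full forward model: (snapshot, intermediate, ideal) from one HR cube."""
    intermediate = apply_spectral_response(hr, sensor.measured, sensor.grid)
    snapshot = mosaic_subsample(intermediate, sensor.pattern)
    ideal = make_ideal_hypercube(hr, sensor.ideal, sensor.grid)
    return PairedSample(snapshot, intermediate, ideal)
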
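"""Spectral-to-sRGB rendering of reconstructed hypercubes.

Reflectance spectra are integrated against the CIE 1931 2-degree standard
observer under the D65 daylight illuminant to obtain CIE XYZ tristimulus
values, which are then mapped to linear sRGB with the standard 3x3 matrix,
clipped to gamut, and gamma-encoded with the piecewise sRGB transfer
function.

The colour-matching functions and the D65 spectral power distribution are
stored as the standard 5 nm CIE tabulations (380-780 nm) and interpolated to
a 1 nm working grid.  The normalisation constant ``k`` is fixed per
colourimetry spec — a perfect reflector seen over the full visible range has
Y = 1 — rather than per image, so brightness errors between reconstructions
stay visible.  A sensor covering only part of the visible range (e.g.
470-620 nm) therefore renders a unit reflector to a fixed, non-white
chromaticity unless the optional white-point rescale is enabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .demosaic import apply_spectral_correction
from .mosaic import Hypercube

__all__ = [
    "ColourimetrySpec",
    "spectra_to_xyz",
    "xyz_to_srgb",
    "srgb_to_xyz",
    "hypercube_to_srgb",
    "CIE_CMF_5NM",
    "D65_5NM",
]

# CIE 1931 2-degree colour-matching functions, 380-780 nm at 5 nm:
# columns are wavelength (nm), x_bar, y_bar, z_bar.
CIE_CMF_5NM = np.array([
    [380, 0.001368, 0.000039, 0.006450],
    [385, 0.002236, 0.000064, 0.010550],
    [390, 0.004243, 0.000120, 0.020050],
    [395, 0.007650, 0.000217, 0.036210],
    [400, 0.014310, 0.000396, 0.067850],
    [405, 0.023190, 0.000640, 0.110200],
    [410, 0.043510, 0.001210, 0.207400],
    [415, 0.077630, 0.002180, 0.371300],
    [420, 0.134380, 0.004000, 0.645600],
    [425, 0.214770, 0.007300, 1.039050],
    [430, 0.283900, 0.011600, 1.385600],
    [435, 0.328500, 0.016840, 1.622960],
    [440, 0.348280, 0.023000, 1.747060],
    [445, 0.348060, 0.029800, 1.782600],
    [450, 0.336200, 0.038000, 1.772110],
    [455, 0.318700, 0.048000, 1.744100],
    [460, 0.290800, 0.060000, 1.669200],
    [465, 0.251100, 0.073900, 1.528100],
    [470, 0.195360, 0.090980, 1.287640],
    [475, 0.142100, 0.112600, 1.041900],
    [480, 0.095640, 0.139020, 0.812950],
    [485, 0.057950, 0.169300, 0.616200],
    [490, 0.032010, 0.208020, 0.465180],
    [495, 0.014700, 0.258600, 0.353300],
    [500, 0.004900, 0.323000, 0.272000],
    [505, 0.002400, 0.407300, 0.212300],
    [510, 0.009300, 0.503000, 0.158200],
    [515, 0.029100, 0.608200, 0.111700],
    [520, 0.063270, 0.710000, 0.078250],
    [525, 0.109600, 0.793200, 0.057250],
    [530, 0.165500, 0.862000, 0.042160],
    [535, 0.225750, 0.914850, 0.029840],
    [540, 0.290400, 0.954000, 0.020300],
    [545, 0.359700, 0.980300, 0.013400],
    [550, 0.433450, 0.994950, 0.008750],
    [555, 0.512050, 1.000000, 0.005750],
    [560, 0.594500, 0.995000, 0.003900],
    [565, 0.678400, 0.978600, 0.002750],
    [570, 0.762100, 0.952000, 0.002100],
    [575, 0.842500, 0.915400, 0.001800],
    [580, 0.916300, 0.870000, 0.001650],
    [585, 0.978600, 0.816300, 0.001400],
    [590, 1.026300, 0.757000, 0.001100],
    [595, 1.056700, 0.694900, 0.001000],
    [600, 1.062200, 0.631000, 0.000800],
    [605, 1.045600, 0.566800, 0.000600],
    [610, 1.002600, 0.503000, 0.000340],
    [615, 0.938400, 0.441200, 0.000240],
    [620, 0.854450, 0.381000, 0.000190],
    [625, 0.751400, 0.321000, 0.000100],
    [630, 0.642400, 0.265000, 0.000050],
    [635, 0.541900, 0.217000, 0.000030],
    [640, 0.447900, 0.175000, 0.000020],
    [645, 0.360800, 0.138200, 0.000010],
    [650, 0.283500, 0.107000, 0.000000],
    [655, 0.218700, 0.081600, 0.000000],
    [660, 0.164900, 0.061000, 0.000000],
    [665, 0.121200, 0.044580, 0.000000],
    [670, 0.087400, 0.032000, 0.000000],
    [675, 0.063600, 0.023200, 0.000000],
    [680, 0.046770, 0.017000, 0.000000],
    [685, 0.032900, 0.011920, 0.000000],
    [690, 0.022700, 0.008210, 0.000000],
    [695, 0.015840, 0.005723, 0.000000],
    [700, 0.011359, 0.004102, 0.000000],
    [705, 0.008111, 0.002929, 0.000000],
    [710, 0.005790, 0.002091, 0.000000],
    [715, 0.004109, 0.001484, 0.000000],
    [720, 0.002899, 0.001047, 0.000000],
    [725, 0.002049, 0.000740, 0.000000],
    [730, 0.001440, 0.000520, 0.000000],
    [735, 0.001000, 0.000361, 0.000000],
    [740, 0.000690, 0.000249, 0.000000],
    [745, 0.000476, 0.000172, 0.000000],
    [750, 0.000332, 0.000120, 0.000000],
    [755, 0.000235, 0.000085, 0.000000],
    [760, 0.000166, 0.000060, 0.000000],
    [765, 0.000117, 0.000042, 0.000000],
    [770, 0.000083, 0.000030, 0.000000],
    [775, 0.000059, 0.000021, 0.000000],
    [780, 0.000042, 0.000015, 0.000000],
])

# CIE standard illuminant D65 relative spectral power, 380-780 nm at 5 nm,
# normalised to 100 at 560 nm: columns wavelength (nm), power.
D65_5NM = np.array([
    [380, 49.98], [385, 52.31], [390, 54.65], [395, 68.70], [400, 82.75],
    [405, 87.12], [410, 91.49], [415, 92.46], [420, 93.43], [425, 90.06],
    [430, 86.68], [435, 95.77], [440, 104.86], [445, 110.94], [450, 117.01],
    [455, 117.41], [460, 117.81], [465, 116.34], [470, 114.86], [475, 115.39],
    [480, 115.92], [485, 112.37], [490, 108.81], [495, 109.08], [500, 109.35],
    [505, 108.58], [510, 107.80], [515, 106.30], [520, 104.79], [525, 106.24],
    [530, 107.69], [535, 106.05], [540, 104.41], [545, 104.23], [550, 104.05],
    [555, 102.02], [560, 100.00], [565, 98.17], [570, 96.33], [575, 96.06],
    [580, 95.79], [585, 92.24], [590, 88.69], [595, 89.35], [600, 90.01],
    [605, 89.80], [610, 89.60], [615, 88.65], [620, 87.70], [625, 85.49],
    [630, 83.29], [635, 83.49], [640, 83.70], [645, 81.86], [650, 80.03],
    [655, 80.12], [660, 80.21], [665, 81.25], [670, 82.28], [675, 80.28],
    [680, 78.28], [685, 74.00], [690, 69.72], [695, 70.67], [700, 71.61],
    [705, 72.98], [710, 74.35], [715, 67.98], [720, 61.60], [725, 65.74],
    [730, 69.89], [735, 72.49], [740, 75.09], [745, 69.34], [750, 63.59],
    [755, 55.01], [760, 46.42], [765, 56.61], [770, 66.81], [775, 65.09],
    [780, 63.38],
])

# IEC 61966-2-1 sRGB primaries under D65; the XYZ->RGB matrix is the exact
# inverse so the transfer round-trips to numerical precision.
RGB_TO_XYZ = np.array([
    [0.4124, 0.3576, 0.1805],
    [0.2126, 0.7152, 0.0722],
    [0.0193, 0.1192, 0.9505],
])
XYZ_TO_RGB = np.linalg.inv(RGB_TO_XYZ)


@dataclass(frozen=True)
class ColourimetrySpec:
    """Observer + illuminant + display primaries used for rendering.

    ``wavelengths`` is the working grid (nm); ``cmf`` the (N, 3) observer
    curves on it; ``illuminant`` the (N,) relative spectral power.  ``k``
    normalises a perfect reflector over the full grid to Y = 1.
    """

    wavelengths: np.ndarray
    cmf: np.ndarray
    illuminant: np.ndarray
    xyz_to_rgb: np.ndarray = None
    rgb_to_xyz: np.ndarray = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=np.float64)
        cmf = np.asarray(self.cmf, dtype=np.float64)
        ill = np.asarray(self.illuminant, dtype=np.float64)
        if cmf.shape != (wl.size, 3) or ill.shape != (wl.size,):
            raise ValueError("cmf/illuminant shapes must match the grid")
        if np.any(cmf < 0):
            raise ValueError("colour-matching functions must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "cmf", cmf)
        object.__setattr__(self, "illuminant", ill)
        if self.xyz_to_rgb is None:
            object.__setattr__(self, "xyz_to_rgb", XYZ_TO_RGB)
            object.__setattr__(self, "rgb_to_xyz", RGB_TO_XYZ)

    @property
    def k(self) -> float:
        w = _trapz_weights(self.wavelengths)
        return 1.0 / float(np.sum(self.illuminant * self.cmf[:, 1] * w))

    def white_point(self) -> np.ndarray:
        """XYZ of a perfect reflector over the full grid (Y = 1)."""
        w = _trapz_weights(self.wavelengths)
        return self.k * (self.illuminant * w) @ self.cmf

    @classmethod
    def d65_2deg(cls, step: float = 1.0) -> "ColourimetrySpec":
        """CIE 1931 2-degree observer under D65 on a ``step``-nm grid."""
        wl = np.arange(380.0, 780.0 + step / 2, step)
        cmf = np.column_stack(
            [
                PchipInterpolator(CIE_CMF_5NM[:, 0], CIE_CMF_5NM[:, j])(wl)
                for j in (1, 2, 3)
            ]
        )
        ill = PchipInterpolator(D65_5NM[:, 0], D65_5NM[:, 1])(wl)
        return cls(wl, np.clip(cmf, 0.0, None), ill)


def _trapz_weights(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.size == 1:
        return np.ones(1)
    w = np.empty_like(x)
    w[0] = (x[1] - x[0]) / 2.0
    w[-1] = (x[-1] - x[-2]) / 2.0
    if x.size > 2:
        w[1:-1] = (x[2:] - x[:-2]) / 2.0
    return w


def spectra_to_xyz(cube: Hypercube, spec: ColourimetrySpec) -> np.ndarray:
    """Integrate reflectance bands against illuminant-weighted observer curves.

    ``XYZ[p] = k * sum_b cube[p, b] * E(l_b) * cmf(l_b) * dl_b`` with
    trapezoidal band weights; linear in the cube values.  Bands outside the
    observer grid contribute nothing (truncation, no extrapolation).
    """
    lb = cube.band_centers
    lo, hi = spec.wavelengths[0], spec.wavelengths[-1]
    inside = (lb >= lo) & (lb <= hi)
    cmf_b = np.zeros((lb.size, 3))
    ill_b = np.zeros(lb.size)
    if inside.any():
        for j in range(3):
            cmf_b[inside, j] = np.interp(lb[inside], spec.wavelengths, spec.cmf[:, j])
        ill_b[inside] = np.interp(lb[inside], spec.wavelengths, spec.illuminant)
    if not np.any(cmf_b[:, 1] * ill_b > 0):
        raise ValueError("no cube band overlaps the observer's support")
    w = _trapz_weights(lb)
    kernel = spec.k * (ill_b * w)[:, None] * cmf_b  # (B, 3)
    return cube.data @ kernel


def _gamma_encode(linear: np.ndarray) -> np.ndarray:
    a = 0.055
    out = np.where(
        linear <= 0.0031308,
        12.92 * linear,
        (1 + a) * np.power(np.clip(linear, 0.0031308, None), 1 / 2.4) - a,
    )
    return out


def _gamma_decode(srgb: np.ndarray) -> np.ndarray:
    a = 0.055
    return np.where(
        srgb <= 0.04045,
        srgb / 12.92,
        np.power((srgb + a) / (1 + a), 2.4),
    )


def xyz_to_srgb(xyz: np.ndarray, as_uint8: bool = True) -> np.ndarray:
    """XYZ image (..., 3) to sRGB: matrix transform, clip to [0, 1] gamut,
    piecewise gamma, and (by default) round-half-up 8-bit quantisation."""
    xyz = np.asarray(xyz, dtype=np.float64)
    linear = np.clip(xyz @ XYZ_TO_RGB.T, 0.0, 1.0)
    srgb = _gamma_encode(linear)
    if as_uint8:
        return np.floor(srgb * 255.0 + 0.5).astype(np.uint8)
    return srgb


def srgb_to_xyz(srgb: np.ndarray) -> np.ndarray:
    """Inverse of :func:`xyz_to_srgb` on the unclipped gamut (float input)."""
    srgb = np.asarray(srgb, dtype=np.float64)
    if srgb.dtype == np.uint8 or srgb.max() > 1.0 + 1e-9:
        srgb = srgb / 255.0
    return _gamma_decode(srgb) @ RGB_TO_XYZ.T


def hypercube_to_srgb(
    cube: Hypercube,
    sensor=None,
    spec: ColourimetrySpec | None = None,
    as_uint8: bool = True,
    whitepoint_rescale: bool = False,
) -> np.ndarray:
    """Render a reconstructed hypercube to sRGB.

    If the cube still carries the sensor's ns measured bands, the
    calibration matrix is applied first; ideal-band cubes are rendered
    directly.  ``whitepoint_rescale`` compensates the truncated visible-range
    integral of narrow sensors so a unit reflector renders white (off by
    default: truncation is a property of the sensor worth seeing).
    """
    spec = ColourimetrySpec.d65_2deg() if spec is None else spec
    if sensor is not None and cube.n_bands == sensor.ns and sensor.ni != sensor.ns:
        cube = apply_spectral_correction(
            cube, sensor.calibration, sensor.ideal.band_centers()
        )
    xyz = spectra_to_xyz(cube, spec)
    if whitepoint_rescale:
        unit = Hypercube(
            np.ones((1, 1, cube.n_bands)), cube.band_centers, cube.role
        )
        y_unit = spectra_to_xyz(unit, spec)[0, 0, 1]
        if y_unit > 0:
            xyz = xyz / y_unit
    return xyz_to_srgb(xyz, as_uint8=as_uint8)
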
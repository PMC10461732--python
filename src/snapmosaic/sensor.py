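"""Spectral model of a snapshot-mosaic hyperspectral sensor.

A snapshot-mosaic camera tiles an ``n x n`` spectral filter array over the
pixel grid, so a single exposure samples ``ns <= n**2`` spectral bands, one
band per pixel.  Each filter is a Fabry-Perot resonator whose ideal band-pass
response is a Lorentzian in optical frequency; real filters additionally show
parasitic harmonics, cross-talk and spectral leakage.  This module holds:

* the wavelength grid and its quadrature weights,
* ideal band specifications (centre wavelength, quantum efficiency, FWHM)
  and their Lorentzian response curves,
* measured (parasitic-affected) response matrices, and a synthesiser that
  perturbs ideal responses into plausible measured ones,
* the spectral-correction calibration matrix ``C`` (ni x ns) mapping measured
  band values to ideal band values, obtained by ridge-regularised least
  squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WavelengthGrid",
    "IdealBandSpec",
    "SpectralResponseMatrix",
    "CalibrationMatrix",
    "MosaicPattern",
    "SensorModel",
    "lorentzian_alpha",
    "lorentzian_response",
    "build_response_matrix",
    "synthesize_measured_responses",
    "compute_calibration_matrix",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis (nm) with trapezoidal quadrature
    weights, so band integrals are invariant to grid resampling density."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavelength grid needs at least two values")
        if not np.all(np.diff(values) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(values > 0):
            raise ValueError("wavelengths must be positive")
        object.__setattr__(self, "values", values)

    @property
    def weights(self) -> np.ndarray:
        """Trapezoidal quadrature weights (nm per sample)."""
        v = self.values
        w = np.empty_like(v)
        w[0] = (v[1] - v[0]) / 2.0
        w[-1] = (v[-1] - v[-2]) / 2.0
        w[1:-1] = (v[2:] - v[:-2]) / 2.0
        return w

    def __len__(self) -> int:
        return self.values.size

    @classmethod
    def regular(cls, start: float, stop: float, step: float) -> "WavelengthGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))


@dataclass(frozen=True)
class IdealBandSpec:
    """Ideal Fabry-Perot band: centre ``lambda0`` (nm), peak quantum
    efficiency ``qe`` in (0, 1], and full-width at half-maximum (nm)."""

    lambda0: float
    qe: float
    fwhm: float

    def __post_init__(self) -> None:
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if not (0 < self.qe <= 1):
            raise ValueError("qe must be in (0, 1]")


@dataclass(frozen=True)
class SpectralResponseMatrix:
    """Band responsivities sampled on a wavelength grid: one row per band."""

    responses: np.ndarray
    grid: WavelengthGrid
    band_labels: tuple = ()

    def __post_init__(self) -> None:
        responses = np.asarray(self.responses, dtype=np.float64)
        if responses.ndim != 2:
            raise ValueError("responses must be a 2-D matrix (bands x wavelengths)")
        if responses.shape[1] != len(self.grid):
            raise ValueError("response column count must equal grid length")
        if np.any(responses < 0) or not np.all(np.isfinite(responses)):
            raise ValueError("responsivities must be finite and non-negative")
        object.__setattr__(self, "responses", responses)
        if not self.band_labels:
            object.__setattr__(
                self, "band_labels", tuple(range(responses.shape[0]))
            )

    @property
    def n_bands(self) -> int:
        return self.responses.shape[0]

    def band_centers(self) -> np.ndarray:
        """Response-weighted centre wavelength of each band (nm)."""
        w = self.grid.weights
        num = self.responses * (self.grid.values * w)
        den = self.responses * w
        return num.sum(axis=1) / den.sum(axis=1)


@dataclass(frozen=True)
class CalibrationMatrix:
    """Linear spectral correction ``C`` (ni x ns): ideal = C @ measured."""

    c: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=np.float64)
        if c.ndim != 2:
            raise ValueError("C must be a matrix")
        if not np.all(np.isfinite(c)):
            raise ValueError("C must be finite")
        object.__setattr__(self, "c", c)

    @property
    def ni(self) -> int:
        return self.c.shape[0]

    @property
    def ns(self) -> int:
        return self.c.shape[1]


@dataclass(frozen=True)
class MosaicPattern:
    """``n x n`` filter-array layout: ``assignment[r, c]`` is the band index
    sampled at block cell (r, c).  Default is row-major ``b = r * n + c``."""

    n: int
    assignment: np.ndarray

    def __post_init__(self) -> None:
        assignment = np.asarray(self.assignment, dtype=np.intp)
        if assignment.shape != (self.n, self.n):
            raise ValueError("assignment must be an n x n grid")
        if assignment.min() < 0 or assignment.max() >= self.n * self.n:
            raise ValueError("band indices must lie in [0, n*n)")
        object.__setattr__(self, "assignment", assignment)

    @property
    def n_bands(self) -> int:
        return int(np.unique(self.assignment).size)

    @classmethod
    def row_major(cls, n: int) -> "MosaicPattern":
        return cls(n, np.arange(n * n).reshape(n, n))


@dataclass(frozen=True)
class SensorModel:
    """Complete sensor description used by the forward and inverse pipelines."""

    grid: WavelengthGrid
    measured: SpectralResponseMatrix
    ideal: SpectralResponseMatrix
    calibration: CalibrationMatrix
    pattern: MosaicPattern
    name: str = "sensor"

    def __post_init__(self) -> None:
        if self.measured.n_bands != self.pattern.n_bands:
            raise ValueError("measured band count must match mosaic pattern")
        if self.calibration.c.shape != (self.ideal.n_bands, self.measured.n_bands):
            raise ValueError("calibration matrix shape must be ni x ns")

    @property
    def ns(self) -> int:
        return self.measured.n_bands

    @property
    def ni(self) -> int:
        return self.ideal.n_bands


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def lorentzian_alpha(lambda0: float, fwhm: float) -> float:
    """Shape parameter of the Fabry-Perot Lorentzian band-pass.

    ``alpha = (sqrt(lambda0**2 + fwhm**2) - lambda0)**2 / fwhm**2`` is the
    unique value for which the response's two half-maximum crossings are
    separated by exactly ``fwhm`` nanometres.
    """
    if lambda0 <= 0 or fwhm <= 0:
        raise ValueError("lambda0 and fwhm must be positive")
    return (np.hypot(lambda0, fwhm) - lambda0) ** 2 / fwhm**2


def lorentzian_response(grid: WavelengthGrid, spec: IdealBandSpec) -> np.ndarray:
    """Ideal band response ``f(l) = qe * a*l^2 / ((l - l0)^2 + a*l^2)``.

    Strictly positive, bounded by ``qe`` with equality only at ``l = l0``.
    """
    a = lorentzian_alpha(spec.lambda0, spec.fwhm)
    lam = grid.values
    al2 = a * lam**2
    # qe * (ratio): the ratio is exactly 1 at lambda0, so the peak is qe
    return spec.qe * (al2 / ((lam - spec.lambda0) ** 2 + al2))


def build_response_matrix(
    grid: WavelengthGrid, specs: list[IdealBandSpec]
) -> SpectralResponseMatrix:
    """Stack Lorentzian responses for ``specs`` into a bands x wavelengths matrix."""
    if len(specs) == 0:
        raise ValueError("need at least one band spec")
    rows = np.stack([lorentzian_response(grid, s) for s in specs])
    return SpectralResponseMatrix(rows, grid)


def synthesize_measured_responses(
    ideal: SpectralResponseMatrix,
    cross_talk: float = 0.0,
    harmonic: float = 0.0,
    leakage: float = 0.0,
    seed: int = 0,
) -> SpectralResponseMatrix:
    """Perturb ideal responses into plausible factory-measured ones.

    Models three parasitic effects of real mosaic filters:

    * ``cross_talk``: convex mixing of each band with its spectral
      neighbours (fraction of energy shared with adjacent rows),
    * ``harmonic``: one secondary Lorentzian peak per band at a
      seed-randomised alias position inside the grid range, with peak
      amplitude ``harmonic`` relative to the band's maximum,
    * ``leakage``: a broadband floor — every entry is raised to at least
      ``leakage`` times the row maximum.

    Deterministic given ``seed``; with all perturbations zero the output
    equals the input exactly.
    """
    for nm, v in (("cross_talk", cross_talk), ("harmonic", harmonic), ("leakage", leakage)):
        if v < 0:
            raise ValueError(f"{nm} must be non-negative")

    rows = ideal.responses.copy()
    nb = rows.shape[0]
    rng = np.random.default_rng(seed)

    if cross_talk > 0 and nb > 1:
        mixed = np.empty_like(rows)
        for i in range(nb):
            neigh = [rows[j] for j in (i - 1, i + 1) if 0 <= j < nb]
            mixed[i] = (1 - cross_talk) * rows[i] + cross_talk * np.mean(neigh, axis=0)
        rows = mixed

    if harmonic > 0:
        lam = ideal.grid.values
        lo, hi = lam[0], lam[-1]
        centers = rng.uniform(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo), size=nb)
        widths = rng.uniform(8.0, 20.0, size=nb)
        for i in range(nb):
            peak = harmonic * rows[i].max()
            sec = lorentzian_response(
                ideal.grid, IdealBandSpec(centers[i], 1.0, widths[i])
            )
            rows[i] = rows[i] + peak * sec

    if leakage > 0:
        floor = leakage * rows.max(axis=1, keepdims=True)
        rows = np.maximum(rows, floor)

    return SpectralResponseMatrix(rows, ideal.grid, ideal.band_labels)


def compute_calibration_matrix(
    measured: SpectralResponseMatrix,
    ideal: SpectralResponseMatrix,
    ridge: float = 1e-6,
) -> CalibrationMatrix:
    """Spectral-correction matrix by ridge-regularised least squares.

    Minimises ``||C @ M - I||_F**2 + ridge_eff * ||C||_F**2`` in closed form,
    where ``M`` (ns x nd) are the measured responses and ``I`` (ni x nd) the
    ideal ones.  ``ridge`` is scaled by ``trace(M M^T) / ns`` so the default
    is dimensionless; a raw pseudo-inverse is unstable when parasitic
    responses make rows of ``M`` near-collinear.
    """
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    if len(measured.grid) != len(ideal.grid) or not np.allclose(
        measured.grid.values, ideal.grid.values
    ):
        raise ValueError("measured and ideal responses must share a wavelength grid")

    m = measured.responses
    gram = m @ m.T
    ns = m.shape[0]
    ridge_eff = ridge * np.trace(gram) / ns
    rhs = ideal.responses @ m.T
    # C solves C (MM^T + rI) = I M^T  =>  (MM^T + rI)^T C^T = (I M^T)^T
    c = np.linalg.solve(gram + ridge_eff * np.eye(ns), rhs.T).T
    return CalibrationMatrix(c)
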
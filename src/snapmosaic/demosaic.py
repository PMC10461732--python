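"""Baseline demosaicking: band splitting, bilinear upsampling, correction.

The snapshot image carries one spectral band per pixel.  The linear baseline
reconstruction (a) groups pixels by the band they sample, (b) bilinearly
interpolates each band's sparse lattice back to the full frame along X and Y,
and (c) applies the spectral-correction matrix ``C`` per pixel to map the ns
measured bands onto the ni ideal bands.

Lattices are offset-aware: each band's samples stay at their true sensor
coordinates (their phase (r, c) inside the mosaic block), which avoids the
inter-band misregistration that collapsing every band onto a common decimated
grid would introduce.  Outside a band's outermost samples, values are clamped
to the nearest lattice row/column (replication), which preserves monotonicity
at frame borders.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import NearestNDInterpolator

from .mosaic import Hypercube, SnapshotMosaic
from .sensor import CalibrationMatrix, SensorModel

__all__ = [
    "split_bands",
    "bilinear_demosaick",
    "apply_spectral_correction",
    "linear_pipeline",
]


def split_bands(snapshot: SnapshotMosaic) -> dict:
    """Group snapshot pixels by sampled band.

    Returns ``{band: (positions, values)}`` where ``positions`` is a (k, 2)
    integer array of (x, y) pixel coordinates and ``values`` the snapshot
    values there.  The groups are disjoint and cover every pixel.
    """
    band = snapshot.band_map()
    out = {}
    for b in np.unique(snapshot.pattern.assignment):
        mask = band == b
        xs, ys = np.nonzero(mask)
        out[int(b)] = (np.column_stack([xs, ys]), snapshot.image[mask])
    return out


def _lerp(a: np.ndarray, b: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Linear interpolation ``a + t (b - a)`` that is exact at both ends."""
    return np.where(t >= 1.0, b, a + t * (b - a))


def _interp_weights(coords: np.ndarray, targets: np.ndarray):
    """1-D bilinear weights of ``targets`` against sorted sample ``coords``,
    with clamp (replication) outside the sample range."""
    if coords.size == 1:
        idx = np.zeros(targets.size, dtype=np.intp)
        return idx, idx, np.zeros(targets.size)
    lo = np.clip(np.searchsorted(coords, targets, side="right") - 1, 0, coords.size - 2)
    hi = lo + 1
    t = (targets - coords[lo]) / (coords[hi] - coords[lo])
    t = np.clip(t, 0.0, 1.0)  # replicate beyond the lattice hull
    return lo, hi, t


def bilinear_demosaick(snapshot: SnapshotMosaic) -> Hypercube:
    """Upsample every band of a snapshot back to full frame size.

    At a band's own lattice positions the output equals the snapshot value
    exactly; elsewhere it is separable bilinear interpolation on that band's
    offset lattice.  Bands whose lattice cells do not form a rectangular
    row x column product set (possible with repeated assignments) fall back
    to nearest-sample filling; bands with no samples at all (frames smaller
    than the block) are zero.
    """
    x, y = snapshot.image.shape
    n = snapshot.pattern.n
    bands = np.unique(snapshot.pattern.assignment)
    ns = bands.size
    out = np.empty((x, y, ns), dtype=np.float64)
    xq = np.arange(x, dtype=np.float64)
    yq = np.arange(y, dtype=np.float64)

    for k, b in enumerate(bands):
        cells = np.argwhere(snapshot.pattern.assignment == b)
        r_offsets = np.unique(cells[:, 0])
        c_offsets = np.unique(cells[:, 1])
        rect = cells.shape[0] == r_offsets.size * c_offsets.size
        xs = np.concatenate([r + n * np.arange((x - r + n - 1) // n) for r in r_offsets])
        ys = np.concatenate([c + n * np.arange((y - c + n - 1) // n) for c in c_offsets])
        xs = np.unique(xs[xs < x]).astype(np.float64)
        ys = np.unique(ys[ys < y]).astype(np.float64)
        if xs.size == 0 or ys.size == 0:
            out[:, :, k] = 0.0
            continue
        if not rect:
            # non-rectangular repeated assignment: nearest scattered sample
            mask = snapshot.band_map() == b
            px, py = np.nonzero(mask)
            interp = NearestNDInterpolator(
                np.column_stack([px, py]), snapshot.image[mask]
            )
            gx, gy = np.meshgrid(xq, yq, indexing="ij")
            out[:, :, k] = interp(gx, gy)
            continue
        vals = snapshot.image[np.ix_(xs.astype(np.intp), ys.astype(np.intp))]
        rlo, rhi, tr = _interp_weights(xs, xq)
        clo, chi, tc = _interp_weights(ys, yq)
        v00 = vals[np.ix_(rlo, clo)]
        v01 = vals[np.ix_(rlo, chi)]
        v10 = vals[np.ix_(rhi, clo)]
        v11 = vals[np.ix_(rhi, chi)]
        tr2 = tr[:, None]
        tc2 = tc[None, :]
        # lerp in difference form: bit-exact for constants and at nodes
        r0 = _lerp(v00, v10, tr2)
        r1 = _lerp(v01, v11, tr2)
        out[:, :, k] = _lerp(r0, r1, tc2)

    centers = np.arange(ns, dtype=np.float64)
    return Hypercube(out, centers, role="intermediate")


def apply_spectral_correction(
    cube: Hypercube, c: CalibrationMatrix, band_centers: np.ndarray | None = None
) -> Hypercube:
    """Per-pixel linear spectral correction: ``out[p] = C @ cube[p]``.

    Maps the ns measured bands onto the ni ideal bands at every pixel.
    ``band_centers`` names the ideal band centres; if omitted, nominal
    centres spanning the input's range are attached.
    """
    if cube.n_bands != c.ns:
        raise ValueError(f"cube has {cube.n_bands} bands, C expects {c.ns}")
    out = cube.data @ c.c.T
    if band_centers is None:
        if c.ni == c.ns:
            band_centers = cube.band_centers
        else:
            band_centers = np.linspace(
                cube.band_centers[0], cube.band_centers[-1], c.ni
            )
    return Hypercube(out, band_centers, role="ideal")


def linear_pipeline(snapshot: SnapshotMosaic, sensor: SensorModel) -> Hypercube:
    """Baseline linear demosaicking: bilinear upsampling then correction by C."""
    cube = bilinear_demosaick(snapshot)
    cube = Hypercube(cube.data, sensor.measured.band_centers(), role="intermediate")
    return apply_spectral_correction(
        cube, sensor.calibration, sensor.ideal.band_centers()
    )
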
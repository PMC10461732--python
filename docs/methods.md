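# Methods

## Problem setting

Snapshot-mosaic hyperspectral cameras tile an `n x n` spectral filter array
over the pixel grid, so one exposure records a scalar image in which each
pixel samples exactly one of `ns <= n^2` spectral bands.  Recovering a full
hypercube from such a frame requires (i) *demosaicking* — restoring the
spatial resolution of every band — and (ii) *spectral correction* — undoing
the parasitic behaviour (cross-talk, harmonics, leakage) of the physical
Fabry-Perot filters.  This package simulates the acquisition from
high-spectral-resolution reflectance cubes, reconstructs hypercubes with a
linear baseline and a learned refinement, renders sRGB previews, and
measures reconstruction quality.

## Sensor model

Each ideal band is a Lorentzian band-pass in wavelength,

    f(λ; λ0, QE, FWHM) = QE · αλ² / ((λ − λ0)² + αλ²),
    α = (sqrt(λ0² + FWHM²) − λ0)² / FWHM²,

with peak responsivity `QE` at the centre wavelength `λ0`.  This α is the
unique choice for which the two half-maximum crossings of `f` are separated
by exactly `FWHM`; the property is enforced by a bisection-oracle test
rather than assumed.  Band integrals use trapezoidal quadrature weights
from the wavelength grid, making projections insensitive to grid
resampling density (verified to 1e-6 relative under grid doubling).

Measured responses are synthesised from the ideal ones by three parasitic
perturbations — convex cross-talk mixing with spectrally adjacent bands, a
single seed-randomised secondary Lorentzian peak per band, and a broadband
leakage floor implemented as a clamp (`entry >= leakage * row maximum`), so
zero perturbation is exactly the identity.  The spectral-correction matrix
`C` (ni x ns) is fitted by ridge-regularised least squares
`min ||C M − I||_F² + r ||C||_F²` with `r` scaled by `trace(M Mᵀ)/ns`
(default 1e-6); the raw pseudo-inverse is unstable when parasitics make
response rows near-collinear.

The bundled default sensor is a visible-range 4x4 mosaic in the mould of
commercial snapshot cameras: 16 measured bands with centres evenly spaced
470–620 nm (FWHM 12 nm, QE 0.55–0.85 peaking mid-spectrum), 13 ideal bands
(475–615 nm, FWHM 15 nm, QE 0.8), row-major band-to-cell assignment, and a
1 nm grid over 440–650 nm.

## Forward simulation

White balancing is flat-field correction `(raw − dark)/(white − dark)`
clipped at zero.  The intermediate cube (X x Y x ns) is the per-pixel inner
product of the measured responses with the (cubically resampled) input
spectrum; the snapshot keeps `intermediate[x, y, assignment[x mod n, y mod n]]`;
the ideal target cube applies the ideal Lorentzian responses the same way.
Frames whose sides are not multiples of `n` keep their partial edge blocks.
Out-of-range wavelengths contribute zero (no spectral extrapolation).

## Reconstruction

*Linear baseline.*  Pixels are grouped by sampled band; each band's sparse
lattice — kept at its true sensor coordinates, i.e. offset by the band's
block phase, to avoid inter-band misregistration — is upsampled by
separable bilinear interpolation, with clamp (replication) beyond the
outermost samples.  The interpolation is implemented in "lerp difference"
form `a + t(b − a)` with an exact branch at `t = 1`, which makes it
bit-exact at sample sites and on constant frames, and exact to rounding on
affine ramps in the lattice interior.  `C` is then applied per pixel.

*Learned refinement.*  A residual U-Net maps the bilinearly demosaicked
ns-band cube to a sharper ns-band cube; `C` is embedded after the network,
and training minimises

    ℓ(ŷs; ys, yi) = ||yi − C ŷs||₁ + γ · aux(ŷs, ys),   γ = 0.001,

where `ys`/`yi` are the intermediate/ideal targets.  The auxiliary term is
either an L1 match to `ys` (default) or a feature-reconstruction term
`||φ(ys) − φ(ŷs)||²` under a frozen 3-channel feature network `φ`, fed one
band at a time as replicated grayscale and averaged over bands (the choice
of band-to-channel adaptation is open; per-band replication avoids
arbitrary triplet picks).  The bundled `φ` is a fixed random-weight
two-stage convolutional extractor — a synthetic stand-in for a pre-trained
classification backbone, adequate for exercising the loss's structure but
not a learned perceptual metric.

The network is an encoder–decoder with residual blocks (two 3x3
convolutions with a leaky-ReLU, slope 0.1, around an additive skip),
channel width doubling at each of `depth` 2x average-pool downsamplings,
nearest-neighbour upsampling, and concatenation skip connections; a global
residual connection adds the input to the output of a zero-initialised
head, so the untrained network is exactly the identity on the bilinear
cube and training can only refine the baseline.  Leaky activations matter
at small training budgets: with plain ReLU and the zero head, a
substantial fraction of units never activates and optimisation stalls.

All tensor operations (im2col convolutions, pooling, upsampling,
concatenation, loss reductions) run on a small reverse-mode autodiff
engine written on numpy, with gradients verified against central finite
differences in the test suite.  The optimiser is Adam; training data are
mosaic-phase-aligned random square patches with flip and 90-degree
rotation augmentation; inputs and targets are normalised by the training
set's maximum intermediate value (the scale is stored in the checkpoint);
the checkpoint with the lowest validation loss is returned.  Everything is
float32 and bit-reproducible given the seeds.

### Training profiles

| parameter        | reference default | desk-scale profile |
|------------------|-------------------|--------------------|
| patch            | 224               | 64                 |
| batch            | 3                 | 3                  |
| depth            | 4                 | 2                  |
| res blocks/level | 2                 | 1                  |
| base width       | 16                | 16                 |
| optimiser        | Adam, lr 1e-4     | Adam, lr 1e-3      |
| iterations       | caller-set        | 500                |

The reference defaults mirror the protocol this architecture is normally
trained under (hours of GPU time over tens of thousands of passes).  The
desk-scale profile, used by the tests and by `scripts/acceptance.py`, is
sized for minutes of single-core CPU time: a 64x64 whole-frame patch on
64x64 phantoms, a shallower and narrower network, and a 10x larger
learning rate because 500 iterations leave no room for a slow schedule.
An optional warmup/cosine-decay schedule exists but the constant schedule
is the default (they performed equivalently at this scale).

## Colorimetry

Reflectance cubes are integrated against the CIE 1931 2-degree
colour-matching functions under the D65 illuminant (standard 5 nm tables
embedded in the source, PCHIP-interpolated to 1 nm; the integrated white
chromaticity lands within 0.02% of the canonical D65 (x, y)).  The
normalisation `k` makes a perfect reflector over the full 380–780 nm grid
have Y = 1 and is fixed per colourimetry spec, *not* per image, so
brightness errors between reconstructions remain visible.  XYZ maps to
linear sRGB through the standard primaries matrix (its exact inverse is
used for the reverse direction, so the transfer round-trips to numerical
precision), is clipped to gamut, gamma-encoded with the piecewise sRGB
curve, and quantised round-half-up to 8 bits.  A sensor covering only
470–620 nm renders a unit reflector to a fixed greenish chromaticity;
an optional white-point rescale (off by default) compensates the
truncated integral for display.

## Metrics

Cube metrics normalise both cubes by the *reference* maximum (PSNR is
range-dependent; the convention is explicit because alternatives differ).
PSNR is `10 log10(1/MSE)` with peak 1, reporting an infinity sentinel for
identical inputs.  SSIM uses the Wang et al. defaults — Gaussian 11x11
window with sigma 1.5, K1 = 0.01, K2 = 0.03, dynamic range 1 — applied per
band and averaged; the implementation delegates to scikit-image and is
cross-checked against a hand-written per-window oracle to 1e-8.  The
perceptual score is an injectable-extractor feature distance; the default
extractor is a deterministic multi-scale gradient pyramid (documented as a
stand-in: scores are comparable within a run, not against published
learned-perceptual numbers).

## Synthetic phantoms

Phantoms emulate white-balanced tissue reflectance at desk scale: per
material (default 4), a smooth spectrum — gentle sloped baseline plus 2–4
Gaussian lobes, rescaled into [0.05, 0.95], redrawn until pairwise L2
distances clear a floor; spatially, blurred Voronoi abundance maps
(convex, summing to 1 at every pixel) mix the materials, and vessel-like
strokes (default 8 per 64x64 frame, random smooth parametric curves with
per-stroke width variation around 1.5 px) attenuate the cube
multiplicatively under a blood-like absorption profile peaking in the
green.  Intraoperative brain-surface scenes are densely vascularised, and
the vessel network is deliberately the dominant high-frequency content:
it is what separates a learned demosaicker from bilinear interpolation.
Optional white Gaussian noise is added and clipped at zero.

What the phantoms do *not* model: radiometric realism of specific
chromophores, specular reflections, depth/defocus, sensor photon and read
noise, and motion.  Passing results on phantoms therefore demonstrate the
pipeline's correctness and the learnability of the super-resolution task
under the simulated sensor, not clinical-grade performance on real
surgical data.

## Numerical choices and degenerate inputs

- Band-to-cell assignment defaults to row-major `b = r·n + c`; real
  layouts are configurable in the sensor file.
- Bands whose mosaic cells do not form a rectangular row x column product
  (repeated assignments) fall back to nearest-sample filling; bands with
  no samples at all (frames smaller than the block) are zero.
- Frames smaller than the block degrade interpolation to nearest-sample;
  this is defined behaviour, not an error.
- `infer` pads reflectively to the network's 2^depth divisibility
  requirement and crops back.
- Training aborts with a diagnostic on a non-finite loss; empty datasets
  and mismatched band counts are rejected up front.
- All randomness flows from explicit seeds; per-stage seeds derive from a
  root seed by stable hashing.

## Known limitations

- The learned-vs-linear margin depends on the phantom's high-frequency
  content: on nearly smooth scenes bilinear interpolation is close to
  optimal and the learned gain shrinks to fractions of a dB.
- The perceptual loss and perceptual score use fixed random-weight
  extractors, not pre-trained networks; they exercise the interfaces and
  loss structure only.
- The numpy training loop is single-core and sized for micro networks;
  the reference-scale protocol is out of reach without a GPU framework.
- Angular dependence of Fabry-Perot filters, optics PSF and noise models
  are not part of the forward model.
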
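# snapmosaic

Simulation and reconstruction toolkit for **snapshot-mosaic hyperspectral
imaging**, aimed at surgical/biomedical imaging research.  Snapshot mosaic
cameras put an `n x n` spectral filter array on the sensor, capturing one
spectral band per pixel in a single exposure — fast enough for
intraoperative use, at the price of an ill-posed *demosaicking* problem and
parasitic spectral behaviour that needs *correction*.  Lacking paired
snapshot/high-resolution acquisitions, the package simulates snapshots from
high-spectral-resolution reflectance cubes with a physical sensor model and
trains a super-resolver on the resulting synthetic pairs.

What it does:

- **Sensor model** — ideal Fabry-Perot band responses (Lorentzian
  `f(λ) = QE·αλ²/((λ−λ0)²+αλ²)` with `α = (√(λ0²+FWHM²)−λ0)²/FWHM²`),
  synthetic parasitics (cross-talk, harmonics, leakage), and a
  ridge-least-squares spectral-correction matrix `C` (ni x ns).
- **Forward simulation** — white balance, spectral projection to the
  intermediate cube (X x Y x ns), mosaic subsampling to the scalar snapshot,
  and the ideal target cube (X x Y x ni).
- **Reconstruction** — bilinear band-wise demosaicking plus per-pixel
  correction by `C` (linear baseline), and a residual U-Net refinement
  trained with the loss `‖yi − Cŷs‖₁ + γ·aux(ŷs, ys)` (γ = 0.001, L1 or
  perceptual auxiliary), implemented on a small numpy autodiff engine.
- **Rendering** — CIE 1931 / D65 integration to XYZ and standard sRGB
  output.
- **Evaluation** — L1, PSNR, SSIM on cubes and renderings, plus a
  pluggable perceptual score.
- **Phantoms** — seeded tissue-like reflectance cubes (smooth material
  spectra, Voronoi regions, vessel-like strokes) so everything runs without
  downloads.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from snapmosaic import (
    PhantomSpec, default_sensor, make_dataset, linear_pipeline,
    bilinear_demosaick, Hypercube, NetworkConfig, TrainConfig, LossConfig,
    train, infer, hypercube_to_srgb,
)
from snapmosaic.metrics import psnr, ssim

sensor = default_sensor(seed=0)                  # 4x4 mosaic, ns=16, ni=13
splits, _ = make_dataset(PhantomSpec(seed=1), sensor, 20, split=(0.6, 0.1, 0.3))

# linear baseline on the 6 held-out phantoms
base = [psnr(s.ideal, linear_pipeline(s.snapshot, sensor)) for s in splits["test"]]

# desk-scale residual U-Net (500 iterations, a few CPU-minutes)
model = train(
    splits["train"], splits["val"],
    NetworkConfig(channels=16, depth=2, res_blocks=1, base_width=16, seed=0),
    LossConfig("l1"),
    TrainConfig(patch=64, batch=3, lr=1e-3, iterations=500, eval_every=100, seed=0),
    calibration=sensor.calibration,
)
learned = []
for s in splits["test"]:
    interp = bilinear_demosaick(s.snapshot)
    interp = Hypercube(interp.data, sensor.measured.band_centers(), "intermediate")
    rec = infer(model, interp, sensor.calibration, sensor.ideal.band_centers())
    learned.append(psnr(s.ideal, rec))

print(f"bilinear {np.mean(base):.2f} dB -> learned {np.mean(learned):.2f} dB")
rgb = hypercube_to_srgb(rec, sensor)             # uint8 sRGB preview
```

On this seeded dataset the run prints

```
bilinear 26.83 dB -> learned 28.33 dB
```

i.e. the learned refinement recovers about 1.5 dB of the spatial detail
that bilinear interpolation blurs away (vessel edges, mostly); SSIM rises
from 0.76 to about 0.86 on the same frames.

A command-line interface wraps the same pipeline:

```sh
snapmosaic --seed 3 make-phantom --count 4 --out cubes/
snapmosaic --seed 3 simulate --in cubes/phantom_000.hdr --out snap.tiff
snapmosaic --seed 3 demosaick --method linear --in snap.tiff --out rec.hdr
snapmosaic --seed 3 rgb --in rec.hdr --out rec.png
snapmosaic --seed 3 run --out artifacts/        # end-to-end incl. training
```

Hypercubes interchange as ENVI (float32 BSQ written; BSQ/BIL/BIP read),
snapshots as 16-bit TIFF with a JSON sidecar, sensors as versioned YAML.

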
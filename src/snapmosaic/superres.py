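"""Learned demosaicking refinement: a residual U-Net super-resolver.

The network maps the bilinearly demosaicked X x Y x ns cube to a sharper
cube of the same size; the spectral-correction matrix ``C`` is embedded
after the network, so training minimises

    loss = || yi - C yhat_s ||_1  +  gamma * aux(yhat_s, ys)

where ``yhat_s`` is the network output, ``ys`` the intermediate target cube,
``yi`` the ideal target cube, and the auxiliary term is either an L1 match
to ``ys`` or a feature-reconstruction (perceptual) term under a frozen
feature network ``phi`` (``gamma`` defaults to 0.001).

Everything runs on a small reverse-mode automatic-differentiation engine
written on numpy (this environment ships no deep-learning framework): 3x3
same-padded convolutions via im2col, ReLU, 2x2 average-pool downsampling,
nearest-neighbour upsampling, channel concatenation and the loss
reductions, with gradients verified against finite differences in the test
suite.  The optimiser is Adam.  All computation is float32 and fully
deterministic given the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .demosaic import apply_spectral_correction, bilinear_demosaick
from .mosaic import Hypercube
from .sensor import CalibrationMatrix

__all__ = [
    "NetworkConfig",
    "LossConfig",
    "TrainConfig",
    "TrainingBatch",
    "ResidualUNet",
    "TrainedModel",
    "build_network",
    "total_loss",
    "train",
    "infer",
]


# ---------------------------------------------------------------------------
# Autodiff engine
# ---------------------------------------------------------------------------


class Tensor:
    """Node of the reverse-mode autodiff graph (data: float32 ndarray)."""

    __slots__ = ("data", "grad", "parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.parents = parents  # tuple of (Tensor, grad_fn)
        self.requires_grad = requires_grad

    def backward(self):
        order, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p, _ in t.parents:
                visit(p)
            order.append(t)

        visit(self)
        for t in order:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t.grad is None:
                continue
            for parent, grad_fn in t.parents:
                g = grad_fn(t.grad)
                parent.grad = g if parent.grad is None else parent.grad + g


def _conv_forward(x: np.ndarray, w: np.ndarray):
    """Same-padded 3x3 correlation; returns output and the im2col patches."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    patches = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    out = np.tensordot(patches, w, axes=([1, 4, 5], [1, 2, 3]))  # (N,H,W,O)
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2)), patches


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3x3 convolution, stride 1, same padding, per-channel bias."""
    out, patches = _conv_forward(x.data, w.data)
    out += b.data[None, :, None, None]

    def grad_x(g):
        # input gradient = same-padded correlation with the spatially
        # flipped kernel, in/out channels swapped
        wt = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        gx, _ = _conv_forward(g, wt)
        return gx

    def grad_w(g):
        return np.tensordot(g, patches, axes=([0, 2, 3], [0, 2, 3])).astype(
            np.float32
        )

    def grad_b(g):
        return g.sum(axis=(0, 2, 3))

    return Tensor(out, ((x, grad_x), (w, grad_w), (b, grad_b)))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, ((x, lambda g: g * mask),))


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    factor = np.where(x.data > 0, np.float32(1.0), np.float32(slope))
    return Tensor(x.data * factor, ((x, lambda g: g * factor),))


def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data + b.data, ((a, lambda g: g), (b, lambda g: g)))


def sub(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data - b.data, ((a, lambda g: g), (b, lambda g: -g)))


def avgpool2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def grad_x(g):
        return np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0

    return Tensor(out, ((x, grad_x),))


def upsample2(x: Tensor) -> Tensor:
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def grad_x(g):
        n, c, h, w = g.shape
        return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    return Tensor(out, ((x, grad_x),))


def concat(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)
    return Tensor(
        out, ((a, lambda g: g[:, :ca]), (b, lambda g: g[:, ca:]))
    )


def apply_matrix(c: np.ndarray, x: Tensor) -> Tensor:
    """Fixed per-pixel channel mixing (the calibration matrix C)."""
    cf = c.astype(np.float32)
    out = np.einsum("oc,nchw->nohw", cf, x.data)
    return Tensor(out, ((x, lambda g: np.einsum("oc,nohw->nchw", cf, g)),))


def mean_abs(x: Tensor) -> Tensor:
    def grad_x(g):
        return g * np.sign(x.data) / x.data.size

    return Tensor(np.mean(np.abs(x.data)), ((x, grad_x),))


def mean_sq(x: Tensor) -> Tensor:
    def grad_x(g):
        return g * 2.0 * x.data / x.data.size

    return Tensor(np.mean(x.data**2), ((x, grad_x),))


def scale(x: Tensor, s: float) -> Tensor:
    return Tensor(x.data * s, ((x, lambda g: g * s),))


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkConfig:
    """Residual U-Net layout: ``depth`` 2x downsamplings with ``res_blocks``
    residual units per resolution, channel width doubling per level, skip
    connections, and a global residual from input to output."""

    channels: int = 16
    depth: int = 4
    res_blocks: int = 2
    base_width: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.res_blocks < 1 or self.base_width < 1:
            raise ValueError("depth, res_blocks and base_width must be >= 1")


def _he_init(rng, shape):
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class ResidualUNet:
    """Encoder-decoder with residual blocks and skip connections.

    The final 3x3 projection is zero-initialised so an untrained network is
    exactly the identity on its input (the bilinear cube): training starts
    from the baseline and can only refine it.
    """

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        self.params: list[Tensor] = []
        rng = np.random.default_rng(cfg.seed)

        def conv_param(cin, cout, zero=False):
            w = Tensor(
                np.zeros((cout, cin, 3, 3), np.float32)
                if zero
                else _he_init(rng, (cout, cin, 3, 3)),
                requires_grad=True,
            )
            b = Tensor(np.zeros(cout, np.float32), requires_grad=True)
            self.params += [w, b]
            return w, b

        def res_params(c):
            return [conv_param(c, c), conv_param(c, c)]

        w0 = cfg.base_width
        self.stem = conv_param(cfg.channels, w0)
        self.enc = []
        widths = [w0 * 2**i for i in range(cfg.depth + 1)]
        for i in range(cfg.depth):
            blocks = [res_params(widths[i]) for _ in range(cfg.res_blocks)]
            down = conv_param(widths[i], widths[i + 1])
            self.enc.append((blocks, down))
        self.mid = [res_params(widths[-1]) for _ in range(cfg.res_blocks)]
        self.dec = []
        for i in reversed(range(cfg.depth)):
            up = conv_param(widths[i + 1], widths[i])
            merge = conv_param(2 * widths[i], widths[i])
            blocks = [res_params(widths[i]) for _ in range(cfg.res_blocks)]
            self.dec.append((up, merge, blocks))
        self.head = conv_param(w0, cfg.channels, zero=True)

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params))

    @staticmethod
    def _res_block(h, block):
        (w1, b1), (w2, b2) = block
        f = conv2d(leaky_relu(conv2d(h, w1, b1)), w2, b2)
        return leaky_relu(add(h, f))

    def forward(self, x: Tensor) -> Tensor:
        """Input and output are (N, ns, H, W); H, W divisible by 2**depth."""
        n, c, h, w = x.data.shape
        div = 2**self.cfg.depth
        if h % div or w % div:
            raise ValueError(
                f"spatial dims ({h}, {w}) must be divisible by {div}; "
                "use infer() for automatic padding"
            )
        hcur = leaky_relu(conv2d(x, *self.stem))
        skips = []
        for blocks, down in self.enc:
            for blk in blocks:
                hcur = self._res_block(hcur, blk)
            skips.append(hcur)
            hcur = leaky_relu(conv2d(avgpool2(hcur), *down))
        for blk in self.mid:
            hcur = self._res_block(hcur, blk)
        for (up, merge, blocks), skip in zip(self.dec, reversed(skips)):
            hcur = leaky_relu(conv2d(upsample2(hcur), *up))
            hcur = leaky_relu(conv2d(concat(hcur, skip), *merge))
            for blk in blocks:
                hcur = self._res_block(hcur, blk)
        out = conv2d(hcur, *self.head)
        return add(x, out)

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state(self, state) -> None:
        for p, s in zip(self.params, state):
            p.data = s.copy()


def build_network(cfg: NetworkConfig) -> ResidualUNet:
    """Construct a residual U-Net; initial parameters are a pure function of
    the config (He-initialised from the config seed, zero head)."""
    return ResidualUNet(cfg)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


class PerceptualFeatures:
    """Frozen random-weight convolutional feature network ``phi``.

    A fixed 3-channel image network (two conv/ReLU stages with pooling,
    seeded random weights, never trained) standing in for a pre-trained
    classification backbone.  Hyperspectral cubes are fed band by band as
    grayscale replicated to three channels and the feature loss is averaged
    over bands.
    """

    def __init__(self, width: int = 8, seed: int = 7):
        rng = np.random.default_rng(seed)
        self.w1 = Tensor(_he_init(rng, (width, 3, 3, 3)))
        self.b1 = Tensor(np.zeros(width, np.float32))
        self.w2 = Tensor(_he_init(rng, (2 * width, width, 3, 3)))
        self.b2 = Tensor(np.zeros(2 * width, np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        h = relu(conv2d(x, self.w1, self.b1))
        h = avgpool2(h)
        return relu(conv2d(h, self.w2, self.b2))


@dataclass(frozen=True)
class LossConfig:
    """Total-loss configuration: mode ``"l1"`` uses an L1 auxiliary match to
    the intermediate target; ``"perceptual"`` a feature-reconstruction term
    under the frozen extractor.  ``gamma`` weights the auxiliary term."""

    mode: str = "l1"
    gamma: float = 0.001
    feature_extractor: object = None

    def __post_init__(self) -> None:
        if self.mode not in ("l1", "perceptual"):
            raise ValueError("mode must be 'l1' or 'perceptual'")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")

    def extractor(self) -> PerceptualFeatures:
        return (
            self.feature_extractor
            if self.feature_extractor is not None
            else _default_extractor()
        )


_EXTRACTOR_CACHE = {}


def _default_extractor() -> PerceptualFeatures:
    if "phi" not in _EXTRACTOR_CACHE:
        _EXTRACTOR_CACHE["phi"] = PerceptualFeatures()
    return _EXTRACTOR_CACHE["phi"]


@dataclass(frozen=True)
class TrainingBatch:
    """One supervised batch: network output ``yhat_s`` (ns bands), the
    intermediate target ``ys`` (ns), the ideal target ``yi`` (ni) and the
    calibration matrix tying them together.  Arrays are (N, C, H, W)."""

    yhat_s: Tensor
    ys: np.ndarray
    yi: np.ndarray
    c: CalibrationMatrix

    def __post_init__(self) -> None:
        ys = np.asarray(self.ys, dtype=np.float32)
        yi = np.asarray(self.yi, dtype=np.float32)
        if self.yhat_s.data.shape != ys.shape:
            raise ValueError("yhat_s and ys must have identical shapes")
        if yi.shape[1] != self.c.ni or ys.shape[1] != self.c.ns:
            raise ValueError("band counts must match the calibration matrix")
        if yi.shape[2:] != ys.shape[2:] or yi.shape[0] != ys.shape[0]:
            raise ValueError("spatial shapes must agree")
        object.__setattr__(self, "ys", ys)
        object.__setattr__(self, "yi", yi)


def total_loss(batch: TrainingBatch, loss_cfg: LossConfig) -> Tensor:
    """Combined training loss (scalar graph node, differentiable w.r.t.
    the network output):

    main term: mean | yi - C yhat_s |; auxiliary term (weight gamma):
    L1 mode mean | ys - yhat_s |, perceptual mode mean squared feature
    difference | phi(ys) - phi(yhat_s) |^2 averaged over bands."""
    corrected = apply_matrix(batch.c.c, batch.yhat_s)
    main = mean_abs(sub(Tensor(batch.yi), corrected))
    if loss_cfg.gamma == 0:
        return main
    if loss_cfg.mode == "l1":
        aux = mean_abs(sub(Tensor(batch.ys), batch.yhat_s))
    else:
        phi = loss_cfg.extractor()
        bands = batch.ys.shape[1]
        terms = []
        for b in range(bands):
            yb = np.repeat(batch.ys[:, b : b + 1], 3, axis=1)
            # replicate each band to the 3 channels phi expects
            hb_t = _take_band_3ch(batch.yhat_s, b)
            terms.append(mean_sq(sub(phi(Tensor(yb)), phi(hb_t))))
        aux = terms[0]
        for t in terms[1:]:
            aux = add(aux, t)
        aux = scale(aux, 1.0 / bands)
    return add(main, scale(aux, loss_cfg.gamma))


def _take_band_3ch(x: Tensor, b: int) -> Tensor:
    out = np.repeat(x.data[:, b : b + 1], 3, axis=1)

    def grad_x(g):
        gx = np.zeros_like(x.data)
        gx[:, b] = g.sum(axis=1)
        return gx

    return Tensor(out, ((x, grad_x),))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol: Adam with random patch cropping and flip /
    90-degree-rotation augmentation.  ``patch`` crops are aligned to the
    mosaic block so the interpolated input keeps full-frame phase
    statistics.  Defaults follow the reference protocol (patch 224, batch 3,
    lr 1e-4); desk-scale runs use smaller patches, fewer iterations and a
    faster schedule."""

    patch: int = 224
    batch: int = 3
    lr: float = 1e-4
    iterations: int = 1000
    eval_every: int = 25
    augment: bool = True
    schedule: str = "constant"
    warmup: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.patch, self.batch, self.iterations, self.eval_every) < 1:
            raise ValueError("patch, batch, iterations, eval_every must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.schedule not in ("constant", "cosine"):
            raise ValueError("schedule must be 'constant' or 'cosine'")

    def lr_at(self, iteration: int) -> float:
        """Learning rate at a 1-based iteration: optional linear warmup to
        ``lr`` followed by a constant or cosine-decayed schedule."""
        if self.warmup > 0 and iteration <= self.warmup:
            return self.lr * iteration / self.warmup
        if self.schedule == "constant":
            return self.lr
        span = max(self.iterations - self.warmup, 1)
        t = (iteration - self.warmup) / span
        return self.lr * 0.5 * (1.0 + np.cos(np.pi * min(t, 1.0)))


class Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedModel:
    """A trained super-resolver: network, input normalisation scale, the
    calibration matrix it was trained against, and the loss history."""

    net: ResidualUNet
    scale: float
    calibration: CalibrationMatrix
    history: dict = field(default_factory=dict)


def _to_nchw(cube_data: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(cube_data.transpose(2, 0, 1), dtype=np.float32)


def _augment(arrays, rng):
    k = rng.integers(0, 4)
    flip = rng.integers(0, 2)
    out = []
    for a in arrays:
        b = np.rot90(a, k=int(k), axes=(1, 2))
        if flip:
            b = b[:, :, ::-1]
        out.append(np.ascontiguousarray(b))
    return out


def _prepare(samples):
    """Bilinear-demosaick each snapshot once and stack (x, ys, yi) as CHW."""
    prepped = []
    for s in samples:
        x = _to_nchw(bilinear_demosaick(s.snapshot).data)
        ys = _to_nchw(s.intermediate.data)
        yi = _to_nchw(s.ideal.data)
        prepped.append((x, ys, yi))
    return prepped


def train(
    train_samples,
    val_samples,
    net_cfg: NetworkConfig,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainConfig | None = None,
    calibration: CalibrationMatrix | None = None,
) -> TrainedModel:
    """Train the residual U-Net on paired samples.

    Inputs are the bilinearly demosaicked snapshots; targets are the
    intermediate (through the embedded C, the ideal) cubes.  All cubes are
    normalised by the training set's maximum intermediate value.
    ``calibration`` is the sensor's C; if omitted, a least-squares estimate
    from the training cubes is used.  The checkpoint with the lowest
    validation loss is returned together with the training/validation loss
    history.  Raises on an empty dataset or a non-finite loss.
    """
    if len(train_samples) == 0 or len(val_samples) == 0:
        raise ValueError("need at least one training and one validation sample")
    loss_cfg = LossConfig() if loss_cfg is None else loss_cfg
    train_cfg = TrainConfig() if train_cfg is None else train_cfg
    block = train_samples[0].snapshot.pattern.n
    for s in list(train_samples) + list(val_samples):
        if s.intermediate.n_bands != net_cfg.channels:
            raise ValueError("network channel count must equal ns")

    prepped = _prepare(train_samples)
    val_prepped = _prepare(val_samples)
    norm = max(max(ys.max() for _, ys, _ in prepped), 1e-12)
    prepped = [(x / norm, ys / norm, yi / norm) for x, ys, yi in prepped]
    val_prepped = [(x / norm, ys / norm, yi / norm) for x, ys, yi in val_prepped]

    net = build_network(net_cfg)
    opt = Adam(net.params, train_cfg.lr)
    rng = np.random.default_rng(train_cfg.seed)
    div = 2**net_cfg.depth
    patch = train_cfg.patch - train_cfg.patch % max(div, block)
    patch = max(patch, max(div, block))

    def crop(arrays, cx, cy):
        return [a[:, cx : cx + patch, cy : cy + patch] for a in arrays]

    history = {"iteration": [], "train_loss": [], "val_iteration": [], "val_loss": []}
    best = (np.inf, net.state())

    def val_loss(calibration):
        losses = []
        for x, ys, yi in val_prepped:
            h, w = x.shape[1:]
            hc, wc = h - h % div, w - w % div
            xb = x[None, :, :hc, :wc]
            out = net.forward(Tensor(xb))
            batch = TrainingBatch(
                out, ys[None, :, :hc, :wc], yi[None, :, :hc, :wc], calibration
            )
            losses.append(float(total_loss(batch, loss_cfg).data))
        return float(np.mean(losses))

    if calibration is None:
        calibration = _infer_calibration(train_samples)

    for it in range(1, train_cfg.iterations + 1):
        xs, yss, yis = [], [], []
        for _ in range(train_cfg.batch):
            x, ys, yi = prepped[rng.integers(0, len(prepped))]
            h, w = x.shape[1:]
            if h < patch or w < patch:
                raise ValueError("patch size exceeds image dimensions")
            cx = (rng.integers(0, (h - patch) // block + 1)) * block
            cy = (rng.integers(0, (w - patch) // block + 1)) * block
            arrs = crop([x, ys, yi], cx, cy)
            if train_cfg.augment:
                arrs = _augment(arrs, rng)
            xs.append(arrs[0])
            yss.append(arrs[1])
            yis.append(arrs[2])
        out = net.forward(Tensor(np.stack(xs)))
        batch = TrainingBatch(out, np.stack(yss), np.stack(yis), calibration)
        loss = total_loss(batch, loss_cfg)
        if not np.isfinite(loss.data):
            raise RuntimeError(f"non-finite loss at iteration {it}")
        loss.backward()
        opt.lr = train_cfg.lr_at(it)
        opt.step()
        history["iteration"].append(it)
        history["train_loss"].append(float(loss.data))
        if it % train_cfg.eval_every == 0 or it == train_cfg.iterations:
            vl = val_loss(calibration)
            history["val_iteration"].append(it)
            history["val_loss"].append(vl)
            if vl < best[0]:
                best = (vl, net.state())

    net.load_state(best[1])
    history["best_val_loss"] = best[0]
    return TrainedModel(net, float(norm), calibration, history)


def _infer_calibration(samples) -> CalibrationMatrix:
    """Least-squares C tying each sample's intermediate cube to its ideal
    cube; exact when the samples were simulated with a single sensor."""
    xs = np.concatenate(
        [s.intermediate.data.reshape(-1, s.intermediate.n_bands) for s in samples]
    )
    ys = np.concatenate([s.ideal.data.reshape(-1, s.ideal.n_bands) for s in samples])
    c, *_ = np.linalg.lstsq(xs, ys, rcond=None)
    return CalibrationMatrix(c.T)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def infer(
    model: TrainedModel,
    interpolated: Hypercube,
    c: CalibrationMatrix | None = None,
    band_centers=None,
) -> Hypercube:
    """Refine a bilinearly demosaicked cube and apply spectral correction.

    Pads reflectively to the network's divisibility requirement and crops
    back, so the output matches the input spatially; deterministic (the
    network has no stochastic layers).
    """
    c = model.calibration if c is None else c
    if interpolated.n_bands != model.net.cfg.channels:
        raise ValueError("band count does not match the trained network")
    x = _to_nchw(interpolated.data) / model.scale
    div = 2 ** model.net.cfg.depth
    h, w = x.shape[1:]
    ph = (-h) % div
    pw = (-w) % div
    xp = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    out = model.net.forward(Tensor(xp[None])).data[0, :, :h, :w]
    refined = Hypercube(
        out.transpose(1, 2, 0).astype(np.float64) * model.scale,
        interpolated.band_centers,
        role="intermediate",
    )
    return apply_spectral_correction(refined, c, band_centers)
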
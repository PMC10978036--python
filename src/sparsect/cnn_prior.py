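"""The artifact-recognition CNN and its use as a real-valued image score.

The network is deliberately small: conv 3x3 (40 channels, ReLU) -> conv 3x3
(20 channels, ReLU) -> global average pooling -> dense weighted sum, with no
bias terms anywhere.  Trained with a sigmoid output it is a binary
classifier that separates few-view FBP reconstructions (label 1, streaked)
from full-view ones (label 0, clean).  Dropping the sigmoid leaves the
pre-activation logit, written CNN(X): an unbounded real score that grows
with artifact severity.  That score -- and its gradient with respect to
every input pixel -- is what the variational reconstructor penalises.

Because the network is bias-free and ReLU-activated, the score is
positively homogeneous: CNN(c*X) = c*CNN(X) for c > 0, and CNN(0) = 0.

Everything here is plain numpy: forward convolutions via im2col matrix
multiplication, gradients by hand-written backpropagation, training with
Adam on the binary cross-entropy.  At 7,580 parameters nothing heavier is
warranted, and the same code path serves training, scoring, and the exact
input gradient needed inside the reconstruction loop.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np


class ModelError(ValueError):
    """Invalid model configuration or input."""


@dataclass(frozen=True)
class CnnConfig:
    """Architecture of the classifier."""

    conv1_channels: int = 40
    conv2_channels: int = 20
    kernel_size: int = 3
    use_bias: bool = False
    input_size: int = 128

    def __post_init__(self) -> None:
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ModelError(f"kernel_size must be odd, got {self.kernel_size}")
        if self.conv1_channels < 1 or self.conv2_channels < 1:
            raise ModelError("channel counts must be >= 1")
        if self.input_size < self.kernel_size:
            raise ModelError("input_size must be >= kernel_size")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings: Adam on binary cross-entropy."""

    epochs: int = 200
    val_split: float = 0.10
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.val_split < 1.0):
            raise ModelError(f"val_split must be in (0, 1), got {self.val_split}")
        if self.epochs < 1:
            raise ModelError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ModelError("batch_size must be >= 1")


@dataclass
class TrainingReport:
    """Per-epoch record of the fit."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    learning_rate: float = 1e-3
    batch_size: int = 32

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,train_loss,val_loss,val_acc\n")
            for e, (tl, vl, va) in enumerate(
                    zip(self.train_loss, self.val_loss, self.val_acc), start=1):
                fh.write(f"{e},{tl:.8g},{vl:.8g},{va:.6g}\n")


class CnnPrior:
    """The network with its weights, operating mode, and input scale.

    ``mode`` is "classifier" (sigmoid output in (0, 1)) or "score" (raw
    logit in (-inf, inf)).  ``input_scale`` is a fixed corpus-level
    constant images are divided by before entering the network; it is set
    once at training time so the score is the same fixed function of the
    image during reconstruction.
    """

    def __init__(self, config: CnnConfig, w1, w2, w_dense,
                 b1=None, b2=None, mode: str = "classifier",
                 input_scale: float = 1.0):
        self.config = config
        self.w1 = np.asarray(w1, dtype=np.float64)
        self.w2 = np.asarray(w2, dtype=np.float64)
        self.w_dense = np.asarray(w_dense, dtype=np.float64)
        self.b1 = None if b1 is None else np.asarray(b1, dtype=np.float64)
        self.b2 = None if b2 is None else np.asarray(b2, dtype=np.float64)
        self.mode = mode
        self.input_scale = float(input_scale)

    @property
    def n_parameters(self) -> int:
        n = self.w1.size + self.w2.size + self.w_dense.size
        if self.b1 is not None:
            n += self.b1.size + self.b2.size
        return n

    def to_score_mode(self) -> "CnnPrior":
        """Discard the sigmoid: subsequent calls treat the logit as output."""
        self.mode = "score"
        return self

    # -- persistence --------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            for name, kernel, bias in (("conv1", self.w1, self.b1),
                                       ("conv2", self.w2, self.b2)):
                grp = fh.create_group(name)
                grp.create_dataset("kernel", data=kernel)
                if bias is not None:
                    grp.create_dataset("bias", data=bias)
            fh.create_group("dense").create_dataset("kernel", data=self.w_dense)
            fh.attrs["config"] = json.dumps(asdict(self.config))
            fh.attrs["mode"] = self.mode
            fh.attrs["input_scale"] = self.input_scale

    @classmethod
    def load(cls, path) -> "CnnPrior":
        try:
            with h5py.File(path, "r") as fh:
                config = CnnConfig(**json.loads(fh.attrs["config"]))
                w1 = fh["conv1/kernel"][()]
                w2 = fh["conv2/kernel"][()]
                wd = fh["dense/kernel"][()]
                b1 = fh["conv1/bias"][()] if "bias" in fh["conv1"] else None
                b2 = fh["conv2/bias"][()] if "bias" in fh["conv2"] else None
                mode = str(fh.attrs["mode"])
                scale = float(fh.attrs["input_scale"])
        except (OSError, KeyError) as exc:
            raise ModelError(f"cannot read weights file {path}: {exc}") from exc
        return cls(config, w1, w2, wd, b1, b2, mode=mode, input_scale=scale)


# ---------------------------------------------------------------------
# convolution primitives ("same" zero padding, stride 1)
#
# Activations are channels-last (B, H, W, C) and a k x k correlation is
# evaluated as k^2 shifted channel-mixing matmuls, so all the arithmetic
# lands in BLAS with no im2col gather.
# ---------------------------------------------------------------------


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Correlate x (B, H, W, Cin) with w (Cout, Cin, k, k), same padding.

    The channel mixing for each kernel tap is one matmul over the whole
    padded batch; the tap's spatial offset becomes a shifted-view add.
    """
    b, h, wid, cin = x.shape
    cout, _, k, _ = w.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    if cin * k * k <= 32:
        # few input channels: im2col is small, one fat matmul wins
        taps = [xp[:, di:di + h, dj:dj + wid, :]
                for di in range(k) for dj in range(k)]
        cols = np.stack(taps, axis=4).reshape(-1, cin * k * k)
        wm = np.ascontiguousarray(w.reshape(cout, -1).T, dtype=x.dtype)
        return (cols @ wm).reshape(b, h, wid, cout)
    xpf = xp.reshape(-1, cin)
    h2, w2 = h + 2 * pad, wid + 2 * pad
    out = np.zeros((b, h, wid, cout), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            wm = np.ascontiguousarray(w[:, :, di, dj].T, dtype=x.dtype)
            p = (xpf @ wm).reshape(b, h2, w2, cout)
            out += p[:, di:di + h, dj:dj + wid, :]
    return out


def _conv_weight_grad(x: np.ndarray, dy: np.ndarray, k: int) -> np.ndarray:
    """d(loss)/d(w) for _conv_same: correlate input with output gradient."""
    b, h, wid, cin = x.shape
    cout = dy.shape[-1]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    dym = dy.reshape(-1, cout)
    g = np.empty((cout, cin, k, k), dtype=np.float64)
    for di in range(k):
        for dj in range(k):
            shifted = np.ascontiguousarray(
                xp[:, di:di + h, dj:dj + wid, :]).reshape(-1, cin)
            g[:, :, di, dj] = (shifted.T @ dym).T
    return g


def _conv_input_grad(dy: np.ndarray, w: np.ndarray) -> np.ndarray:
    """d(loss)/d(x) for _conv_same: full correlation with the flipped kernel."""
    w_t = w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
    return _conv_same(dy, np.ascontiguousarray(w_t))


# ---------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------


def _check_input(model: CnnPrior, image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ModelError(f"expected a 2-D image, got shape {image.shape}")
    k = model.config.kernel_size
    if image.shape[0] < k or image.shape[1] < k:
        raise ModelError(
            f"image {image.shape} smaller than the {k}x{k} kernel")
    if not np.all(np.isfinite(image)):
        raise ModelError("image contains non-finite values")
    return image.astype(np.float64)


def _forward_batch(model: CnnPrior, x: np.ndarray):
    """Logits and intermediate activations for a batch (B, H, W)."""
    a0 = (x / model.input_scale)[..., None]  # channels-last
    z1 = _conv_same(a0, model.w1.astype(a0.dtype))
    if model.b1 is not None:
        z1 += model.b1[None, None, None, :]
    a1 = np.maximum(z1, 0.0)
    z2 = _conv_same(a1, model.w2.astype(a0.dtype))
    if model.b2 is not None:
        z2 += model.b2[None, None, None, :]
    a2 = np.maximum(z2, 0.0)
    pooled = a2.mean(axis=(1, 2))  # global average pooling -> (B, C2)
    logits = pooled @ model.w_dense.astype(a0.dtype)
    return logits, (a0, z1, a1, z2, a2, pooled)


def _input_grad_from_dlogit(model: CnnPrior, cache, dlogit: np.ndarray
                            ) -> np.ndarray:
    """Backpropagate d(loss)/d(logit) down to the raw input pixels."""
    a0, z1, a1, z2, _, _ = cache
    h, w = a0.shape[1], a0.shape[2]
    dz2 = (dlogit[:, None, None, None]
           * model.w_dense[None, None, None, :].astype(a0.dtype)
           / (h * w)) * (z2 > 0)
    da1 = _conv_input_grad(dz2, model.w2.astype(a0.dtype))
    dz1 = da1 * (z1 > 0)
    da0 = _conv_input_grad(dz1, model.w1.astype(a0.dtype))
    return da0[..., 0] / model.input_scale


def build_model(config: CnnConfig, seed: int = 0) -> CnnPrior:
    """Initialise the network with fan-in-scaled uniform weights."""
    rng = np.random.default_rng(seed)
    k = config.kernel_size

    def glorot(shape, fan_in):
        lim = np.sqrt(3.0 / fan_in)
        return rng.uniform(-lim, lim, size=shape)

    w1 = glorot((config.conv1_channels, 1, k, k), fan_in=k * k)
    w2 = glorot((config.conv2_channels, config.conv1_channels, k, k),
                fan_in=k * k * config.conv1_channels)
    wd = glorot((config.conv2_channels,), fan_in=config.conv2_channels)
    b1 = b2 = None
    if config.use_bias:
        b1 = np.zeros(config.conv1_channels)
        b2 = np.zeros(config.conv2_channels)
    return CnnPrior(config, w1, w2, wd, b1, b2)


def cnn_score(model: CnnPrior, image: np.ndarray) -> float:
    """The raw (pre-sigmoid) logit: large = artifact-like, small = clean."""
    image = _check_input(model, image)
    logits, _ = _forward_batch(model, image[None])
    return float(logits[0])


def classifier_output(model: CnnPrior, image: np.ndarray) -> float:
    """Probability of the "bad image" class: sigmoid of the score."""
    return float(_sigmoid(np.array([cnn_score(model, image)]))[0])


def cnn_score_gradient(model: CnnPrior, image: np.ndarray) -> np.ndarray:
    """Gradient of the score with respect to every input pixel."""
    image = _check_input(model, image)
    _, cache = _forward_batch(model, image[None])
    g = _input_grad_from_dlogit(model, cache, np.ones(1))
    return g[0]


def feature_maps(model: CnnPrior, image: np.ndarray, layer: int
                 ) -> list[np.ndarray]:
    """Post-ReLU channel maps of conv layer 1 or 2 (edge/streak diagnostics)."""
    if layer not in (1, 2):
        raise ModelError(f"layer must be 1 or 2, got {layer}")
    image = _check_input(model, image)
    _, (_, _, a1, _, a2, _) = _forward_batch(model, image[None])
    maps = a1[0] if layer == 1 else a2[0]  # (H, W, C)
    return [np.ascontiguousarray(maps[..., c]) for c in range(maps.shape[-1])]


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce_from_logits(logits: np.ndarray, y: np.ndarray) -> float:
    # numerically stable: max(s,0) - s*y + log(1 + exp(-|s|))
    return float(np.mean(np.maximum(logits, 0.0) - logits * y
                         + np.log1p(np.exp(-np.abs(logits)))))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _corpus_arrays(corpus) -> tuple[np.ndarray, np.ndarray]:
    if len(corpus) and hasattr(corpus[0], "image"):
        images = np.stack([s.image for s in corpus])
        labels = np.array([s.label for s in corpus], dtype=np.float64)
    else:
        images, labels = corpus
        images = np.asarray(images)
        labels = np.asarray(labels, dtype=np.float64).reshape(-1)
    return images, labels


def train_classifier(model: CnnPrior, corpus, tc: TrainConfig
                     ) -> tuple[CnnPrior, TrainingReport]:
    """Fit the classifier with Adam on binary cross-entropy.

    ``corpus`` is a list of LabeledSample or an (images, labels) pair.
    The validation split is taken after a seeded shuffle; batches are
    reshuffled every epoch from the same generator, so a fixed seed gives
    a bit-reproducible fit on a single thread.  The corpus maximum is
    frozen into ``model.input_scale`` before the first step.
    """
    images, labels = _corpus_arrays(corpus)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ModelError("corpus contains a single class; need both labels")

    scale = float(np.max(images))
    model.input_scale = scale if scale > 0 else 1.0

    rng = np.random.default_rng(tc.seed)
    order = rng.permutation(len(images))
    n_val = max(1, int(round(tc.val_split * len(images))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    x_train = images[train_idx].astype(np.float32)
    y_train = labels[train_idx]
    x_val = images[val_idx].astype(np.float32)
    y_val = labels[val_idx]

    params = {"w1": model.w1, "w2": model.w2, "wd": model.w_dense}
    if model.b1 is not None:
        params.update({"b1": model.b1, "b2": model.b2})
    opt = _Adam(params, lr=tc.learning_rate)
    report = TrainingReport(learning_rate=tc.learning_rate,
                            batch_size=tc.batch_size)

    hw = x_train.shape[1] * x_train.shape[2]
    for _epoch in range(tc.epochs):
        perm = rng.permutation(len(x_train))
        losses = []
        for s in range(0, len(perm), tc.batch_size):
            idx = perm[s:s + tc.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits, cache = _forward_batch(model, xb)
            losses.append(_bce_from_logits(logits, yb))
            a0, z1, a1, z2, _, pooled = cache

            dlogit = ((_sigmoid(logits) - yb) / len(idx)).astype(a0.dtype)
            grads = {"wd": pooled.astype(np.float64).T @ dlogit}
            dz2 = (dlogit[:, None, None, None]
                   * model.w_dense[None, None, None, :].astype(a0.dtype)
                   / hw) * (z2 > 0)
            grads["w2"] = _conv_weight_grad(a1, dz2, model.config.kernel_size)
            da1 = _conv_input_grad(dz2, model.w2.astype(a0.dtype))
            dz1 = da1 * (z1 > 0)
            grads["w1"] = _conv_weight_grad(a0, dz1, model.config.kernel_size)
            if model.b1 is not None:
                grads["b1"] = dz1.sum(axis=(0, 1, 2)).astype(np.float64)
                grads["b2"] = dz2.sum(axis=(0, 1, 2)).astype(np.float64)
            opt.step(params, {k: np.asarray(v, dtype=np.float64)
                              for k, v in grads.items()})

        val_logits, _ = _forward_batch(model, x_val)
        report.train_loss.append(float(np.mean(losses)))
        report.val_loss.append(_bce_from_logits(val_logits, y_val))
        report.val_acc.append(
            float(np.mean((val_logits > 0).astype(float) == y_val)))
    return model, report


def evaluate(model: CnnPrior, corpus) -> float:
    """Classification accuracy of the model on a labelled corpus."""
    images, labels = _corpus_arrays(corpus)
    logits, _ = _forward_batch(model, images.astype(np.float32))
    return float(np.mean((logits > 0).astype(float) == labels))
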
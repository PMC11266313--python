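"""The attention-DFCNN classifier.

A small convolutional network for featured sEMG images: three 3x3
same-padding conv layers with ReLU and channel expansion (1 -> 32 -> 64 ->
128), an additive residual connection bridging the expansion blocks through a
1x1 projection, a squeeze-and-excitation (SE) channel-attention block, and a
dense head (512 -> 256 -> 64 -> n_classes) finishing in LogSoftmax. Dropout
follows the activations of the first two dense layers. The SE block lets the
network down-weight uninformative feature channels — the mechanism that buys
robustness when electrodes are damaged.

The SE block computes, for a feature map ``u`` of shape H x W x C,

    z_c = mean over (h, w) of u[h, w, c]          (squeeze)
    s   = sigmoid(W2 @ relu(W1 @ z))              (excite)
    x~[h, w, c] = s_c * u[h, w, c]                (scale)

with a bottleneck of C / reduction units, so each channel is rescaled by a
learned gate strictly inside (0, 1).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from semgshift.layers import Adam, Conv1x1, Conv3x3, Dense, Param, log_softmax, relu

__all__ = [
    "ModelConfig",
    "AttentionDFCNN",
    "build_model",
    "se_squeeze",
    "se_excite",
    "se_scale",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``input_shape`` is the FSI layout (rows, cols); supported shapes are any
    grid of at least 3 x 3. ``se_reduction`` is the SE bottleneck ratio r
    (C -> C/r -> C). ``se_enabled=False`` builds the identical network with
    the attention gate bypassed (gate fixed at 1); the SE weights are still
    allocated from the same random draws so the two variants share every
    other parameter bit-for-bit.
    """

    input_shape: tuple[int, int]
    n_classes: int = 9
    conv_channels: tuple[int, ...] = (32, 64, 128)
    kernel: tuple[int, int] = (3, 3)
    se_reduction: int = 4
    hidden_units: tuple[int, ...] = (512, 256, 64)
    dropout_rate: float = 0.3
    seed: int = 0
    se_enabled: bool = True
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.kernel != (3, 3):
            raise ValueError("only 3x3 kernels are supported")
        if self.input_shape[0] < 3 or self.input_shape[1] < 3:
            raise ValueError(f"input_shape must be at least 3x3, got {self.input_shape}")
        if len(self.conv_channels) != 3:
            raise ValueError("conv_channels must name three conv layers")
        if any(b <= a for a, b in zip(self.conv_channels[1:], self.conv_channels[2:])):
            raise ValueError("conv_channels must expand after the first layer")
        if not self.conv_channels[-1] % self.se_reduction == 0:
            raise ValueError("se_reduction must divide the last conv width")


def se_squeeze(u: np.ndarray) -> np.ndarray:
    """Global spatial average pooling: H x W x C (or N x H x W x C) -> C (or N x C)."""
    if u.ndim not in (3, 4) or u.shape[-2] == 0 or u.shape[-3] == 0:
        raise ValueError(f"expected a (batch x) H x W x C map with H, W >= 1, got shape {u.shape}")
    return u.mean(axis=(-3, -2))


def se_excite(z: np.ndarray, w1: np.ndarray, b1: np.ndarray, w2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Excitation gate: sigmoid(relu(z @ W1 + b1) @ W2 + b2), each value in (0, 1)."""
    z = np.atleast_2d(z)
    if z.shape[-1] != w1.shape[0] or w1.shape[1] != w2.shape[0] or w2.shape[1] != z.shape[-1]:
        raise ValueError(
            f"inconsistent SE dimensions: z has {z.shape[-1]} channels, "
            f"W1 is {w1.shape}, W2 is {w2.shape}"
        )
    hidden = relu(z @ w1 + b1)
    return 1.0 / (1.0 + np.exp(-(hidden @ w2 + b2)))


def se_scale(u: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Channel-wise rescaling: x~[..., h, w, c] = s_c * u[..., h, w, c]."""
    s = np.asarray(s)
    if s.shape[-1] != u.shape[-1]:
        raise ValueError(f"gate has {s.shape[-1]} channels but map has {u.shape[-1]}")
    if u.ndim == 4 and s.ndim == 2:
        return u * s[:, None, None, :]
    return u * s


class AttentionDFCNN:
    """SE-attention residual CNN over single-channel FSI inputs.

    Weights are drawn from a seeded generator in a fixed order, so two builds
    from the same config are bit-identical. ``se_bypass`` (or building with
    ``se_enabled=False``) forces the attention gate to exactly 1, which
    reduces the network to the plain residual CNN.
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype).type
        self.dtype = dtype
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 909)))
        c1, c2, c3 = cfg.conv_channels
        h, w = cfg.input_shape
        self.conv1 = Conv3x3(1, c1, rng, dtype)
        self.conv2 = Conv3x3(c1, c2, rng, dtype)
        self.conv3 = Conv3x3(c2, c3, rng, dtype)
        self.proj = Conv1x1(c1, c3, rng, dtype)
        bottleneck = c3 // cfg.se_reduction
        self.se_fc1 = Dense(c3, bottleneck, rng, dtype, gain=2.0)
        self.se_fc2 = Dense(bottleneck, c3, rng, dtype, gain=1.0)
        flat = h * w * c3
        dims = [flat, *cfg.hidden_units]
        self.dense = [Dense(dims[i], dims[i + 1], rng, dtype, gain=2.0) for i in range(len(dims) - 1)]
        self.head = Dense(dims[-1], cfg.n_classes, rng, dtype, gain=1.0)
        self.se_bypass = not cfg.se_enabled
        self._cache: dict = {}

    # -- parameter bookkeeping -------------------------------------------------

    @property
    def params(self) -> list[Param]:
        layers = [self.conv1, self.conv2, self.conv3, self.proj]
        if not self.se_bypass:
            layers += [self.se_fc1, self.se_fc2]
        layers += [*self.dense, self.head]
        return [p for layer in layers for p in layer.params]

    def n_parameters(self, include_se: bool = True) -> int:
        layers = [self.conv1, self.conv2, self.conv3, self.proj, *self.dense, self.head]
        if include_se:
            layers += [self.se_fc1, self.se_fc2]
        return sum(p.value.size for layer in layers for p in layer.params)

    # -- forward / backward ----------------------------------------------------

    def _check_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != tuple(self.cfg.input_shape):
            raise ValueError(f"batch shape {x.shape} does not match input_shape {self.cfg.input_shape}")
        return x[..., None]  # NHWC with one input channel

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Log-probabilities, shape (batch, n_classes)."""
        x = self._check_batch(x)
        cache = self._cache
        h1 = relu(self.conv1.forward(x))
        cache["h1"] = h1
        h2 = relu(self.conv2.forward(h1))
        cache["h2"] = h2
        pre = self.conv3.forward(h2) + self.proj.forward(h1)
        u = relu(pre)
        cache["pre"], cache["u"] = pre, u

        if self.se_bypass:
            v = u
            cache["s"] = None
        else:
            z = se_squeeze(u)
            hid = relu(self.se_fc1.forward(z))
            gate_pre = self.se_fc2.forward(hid)
            s = 1.0 / (1.0 + np.exp(-gate_pre))
            v = se_scale(u, s)
            cache["hid"], cache["s"] = hid, s

        n = v.shape[0]
        f = v.reshape(n, -1)
        self._drop_masks = []
        for i, layer in enumerate(self.dense):
            f = relu(layer.forward(f))
            if train and i < 2 and self.cfg.dropout_rate > 0:
                if dropout_rng is None:
                    raise ValueError("training forward pass needs a dropout rng")
                keep = 1.0 - self.cfg.dropout_rate
                mask = (dropout_rng.random(f.shape) < keep).astype(f.dtype) / keep
                f = f * mask
                self._drop_masks.append(mask)
            else:
                self._drop_masks.append(None)
            cache[f"d{i}"] = f
        logits = self.head.forward(f)
        cache["logits"] = logits
        return log_softmax(logits)

    def loss_and_grad(
        self,
        x: np.ndarray,
        y: np.ndarray,
        dropout_rng: np.random.Generator | None = None,
        train: bool = True,
    ) -> float:
        """Mean negative log-likelihood; accumulates gradients into params."""
        logp = self.forward(x, train=train, dropout_rng=dropout_rng)
        n = logp.shape[0]
        loss = -float(logp[np.arange(n), y].mean())

        # d(NLL)/dlogits = (softmax - onehot) / n
        dlogits = np.exp(logp)
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        dlogits = dlogits.astype(self.dtype)

        cache = self._cache
        df = self.head.backward(dlogits)
        for i in reversed(range(len(self.dense))):
            if self._drop_masks[i] is not None:
                df = df * self._drop_masks[i]
            # post-activation cache: its support is the ReLU (and dropout) mask
            df = df * (cache[f"d{i}"] > 0)
            df = self.dense[i].backward(df)

        u = cache["u"]
        nb, hh, ww, cc = u.shape
        dv = df.reshape(nb, hh, ww, cc)
        if self.se_bypass:
            du = dv
        else:
            s = cache["s"]
            du = dv * s[:, None, None, :]
            ds = (dv * u).sum(axis=(1, 2))
            dgate_pre = ds * s * (1.0 - s)
            dhid = self.se_fc2.backward(dgate_pre.astype(self.dtype))
            dhid = dhid * (cache["hid"] > 0)
            dz = self.se_fc1.backward(dhid.astype(self.dtype))
            du = du + dz[:, None, None, :] / (hh * ww)

        dpre = (du * (cache["pre"] > 0)).astype(self.dtype)
        dh2 = self.conv3.backward(dpre)
        dh1 = self.proj.backward(dpre)
        dh2 = dh2 * (cache["h2"] > 0)
        dh1 = dh1 + self.conv2.backward(dh2.astype(self.dtype))
        dh1 = dh1 * (cache["h1"] > 0)
        self.conv1.backward(dh1.astype(self.dtype))
        return loss

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Predicted gesture labels for a stack of FSIs."""
        x = np.asarray(x)
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(np.argmax(self.forward(x[i : i + batch_size]), axis=1))
        return np.concatenate(out)

    def se_gate(self, x: np.ndarray) -> np.ndarray:
        """Attention gate s for a batch of inputs, shape (batch, C)."""
        self.forward(x)
        s = self._cache["s"]
        if s is None:
            return np.ones((np.asarray(x).shape[0], self.cfg.conv_channels[-1]), dtype=self.dtype)
        return s


def build_model(cfg: ModelConfig) -> AttentionDFCNN:
    """Construct a seeded attention-DFCNN from its config."""
    return AttentionDFCNN(cfg)


def make_optimizer(model: AttentionDFCNN, lr: float = 1e-3) -> Adam:
    return Adam(model.params, lr=lr)


def save_model(model: AttentionDFCNN, path) -> None:
    """Serialize weights plus embedded config to a single ``.npz`` checkpoint."""
    cfg_json = json.dumps(asdict(model.cfg))
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params)}
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> AttentionDFCNN:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        for key in ("input_shape", "conv_channels", "kernel", "hidden_units"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = AttentionDFCNN(ModelConfig(**cfg_dict))
        for i, p in enumerate(model.params):
            p.value[...] = data[f"p{i}"]
    return model
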
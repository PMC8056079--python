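"""Network building blocks for the localizer and tracker.

Layers hold their parameters as autodiff Tensors; a model is a plain
Python object exposing ``parameters()`` and a forward ``__call__``.
Group normalization (groups of 8, or the channel count when narrower)
replaces batch normalization throughout, as the training batches are
tiny. Weight layout is documented per layer so models can be stored in
a single ``.npz`` container with a JSON config entry.
"""

from __future__ import annotations

import json

import numpy as np

from ._autodiff import Tensor

IDENTITY_AFFINE_PARAMS = np.array(
    [1, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0], dtype=np.float64)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d:
    def __init__(self, cin, cout, rng, k=3, stride=1, padding=1,
                 zero_init=False):
        self.stride, self.padding = stride, padding
        fan_in = cin * k * k
        w = np.zeros((cout, cin, k, k)) if zero_init else _he_init(
            rng, (cout, cin, k, k), fan_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias,
                        stride=self.stride, padding=self.padding)

    def parameters(self):
        return [self.weight, self.bias]


class Conv3d:
    def __init__(self, cin, cout, rng, k=3, stride=1, padding=1,
                 zero_init=False):
        self.stride, self.padding = stride, padding
        fan_in = cin * k ** 3
        w = np.zeros((cout, cin, k, k, k)) if zero_init else _he_init(
            rng, (cout, cin, k, k, k), fan_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv3d(self.weight, self.bias,
                        stride=self.stride, padding=self.padding)

    def parameters(self):
        return [self.weight, self.bias]


class ConvTranspose3d:
    """Stride-2, kernel-2 transposed convolution (exact doubling)."""

    def __init__(self, cin, cout, rng, stride=2):
        self.stride = stride
        fan_in = cin
        self.weight = Tensor(_he_init(rng, (cin, cout) + (stride,) * 3, fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv_transpose3d(self.weight, self.bias, stride=self.stride)

    def parameters(self):
        return [self.weight, self.bias]


class GroupNorm:
    def __init__(self, channels, groups=8, eps=1e-5):
        self.groups = groups if channels % groups == 0 and channels >= groups \
            else channels
        self.channels = channels
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        sp = x.shape[2:]
        g = self.groups
        xg = x.reshape(n, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        centered = xg - mu
        var = (centered ** 2.0).mean(axis=2, keepdims=True)
        norm = centered * ((var + self.eps) ** -0.5)
        out = norm.reshape((n, c) + sp)
        shape = (1, c) + (1,) * len(sp)
        return out * self.gamma.reshape(shape) + self.beta.reshape(shape)

    def parameters(self):
        return [self.gamma, self.beta]


class Linear:
    def __init__(self, fin, fout, rng, zero_init=False, bias_init=None):
        w = np.zeros((fin, fout)) if zero_init else _he_init(
            rng, (fin, fout), fin)
        self.weight = Tensor(w, requires_grad=True)
        b = np.zeros(fout) if bias_init is None else np.asarray(
            bias_init, dtype=np.float64)
        self.bias = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self):
        return [self.weight, self.bias]


def _gap(x: Tensor) -> Tensor:
    """Global average pooling over all spatial axes -> (N, C)."""
    return x.reshape(x.shape[0], x.shape[1], -1).mean(axis=2)


class SliceScorer2d:
    """VGG-like 2-D convnet mapping an axial slice to a scalar score.

    Strided 3x3 conv blocks (conv -> group norm -> ReLU), global average
    pooling, and a linear head. Width/depth are configurable; defaults
    are sized for CPU training.
    """

    version = 1

    def __init__(self, widths=(8, 16, 32), seed=0):
        self.widths = tuple(int(w) for w in widths)
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.blocks = []
        cin = 1
        for w in self.widths:
            self.blocks.append((Conv2d(cin, w, rng, stride=2), GroupNorm(w)))
            cin = w
        self.head = Linear(cin, 1, rng)

    def parameters(self):
        ps = []
        for conv, gn in self.blocks:
            ps += conv.parameters() + gn.parameters()
        return ps + self.head.parameters()

    def __call__(self, slices: Tensor) -> Tensor:
        """slices: (N, 1, H, W) -> scores (N,)."""
        x = slices
        for conv, gn in self.blocks:
            x = gn(conv(x)).relu()
        return self.head(_gap(x)).reshape(-1)

    def score_array(self, slices: np.ndarray) -> np.ndarray:
        """Score a stack of raw 2-D slices (N, H, W) without grad."""
        return self(Tensor(slices[:, None])).data

    def config(self) -> dict:
        return {"kind": "slice_scorer", "version": self.version,
                "widths": list(self.widths), "seed": self.seed}


class AffineNet3d:
    """Five strided conv blocks + two fully connected layers -> 12
    affine parameters. The head is zero-initialized with an identity
    bias, so the untrained network is the identity transform."""

    version = 1

    def __init__(self, widths=(8, 16, 16, 32, 32), seed=0):
        self.widths = tuple(int(w) for w in widths)
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed + 1)
        self.blocks = []
        cin = 2
        for w in self.widths:
            self.blocks.append((Conv3d(cin, w, rng, stride=2), GroupNorm(w)))
            cin = w
        # zero head: raw outputs are deviations from identity, so the
        # untrained network is exactly the identity transform
        self.fc1 = Linear(cin, cin, rng)
        self.fc2 = Linear(cin, 12, rng, zero_init=True)

    def parameters(self):
        ps = []
        for conv, gn in self.blocks:
            ps += conv.parameters() + gn.parameters()
        return ps + self.fc1.parameters() + self.fc2.parameters()

    def __call__(self, pair: Tensor) -> Tensor:
        """pair: (N, 2, D, H, W) -> raw parameter deviations (N, 12)."""
        x = pair
        for conv, gn in self.blocks:
            x = gn(conv(x)).relu()
        return self.fc2(self.fc1(_gap(x)).relu())

    def config(self) -> dict:
        return {"kind": "affine_net", "version": self.version,
                "widths": list(self.widths), "seed": self.seed}


class UNet3d:
    """U-Net regressing a displacement field from a channel-stacked pair.

    Encoder: four strided conv blocks (widths 16/32/64/96). Latent:
    stride-1 conv with 96 channels -- the deepest layer, whose feature
    maps are pooled into the 96-entry prognostic feature vector.
    Decoder: four transposed-conv blocks with skip connections from the
    matching encoder scale. The final 3-channel conv is zero-initialized
    so the untrained network outputs a zero field.
    """

    version = 1
    LATENT_CHANNELS = 96

    def __init__(self, enc_widths=(16, 32, 64, 96), seed=0):
        if enc_widths[-1] != self.LATENT_CHANNELS:
            raise ValueError("deepest width must equal 96 latent channels")
        self.enc_widths = tuple(int(w) for w in enc_widths)
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed + 2)
        self.enc = []
        cin = 2
        for w in self.enc_widths:
            self.enc.append((Conv3d(cin, w, rng, stride=2), GroupNorm(w)))
            cin = w
        self.latent = (Conv3d(cin, self.LATENT_CHANNELS, rng, stride=1),
                       GroupNorm(self.LATENT_CHANNELS))
        dec_widths = tuple(reversed(self.enc_widths[:-1])) + (
            self.enc_widths[0],)  # 64, 32, 16, 16
        self.dec = []
        cin = self.LATENT_CHANNELS
        skips = list(reversed(self.enc_widths[:-1])) + [0]  # skip channel counts
        for w, sk in zip(dec_widths, skips):
            self.dec.append((ConvTranspose3d(cin, w, rng), GroupNorm(w)))
            cin = w + sk
        self.flow_head = Conv3d(cin, 3, rng, stride=1, zero_init=True)

    def parameters(self):
        ps = []
        for conv, gn in self.enc + [self.latent] + self.dec:
            ps += conv.parameters() + gn.parameters()
        return ps + self.flow_head.parameters()

    def __call__(self, pair: Tensor):
        """pair: (N, 2, D, H, W) -> (flow (N,3,D,H,W), latent (N,96,d,h,w))."""
        x = pair
        enc_feats = []
        for conv, gn in self.enc:
            x = gn(conv(x)).relu()
            enc_feats.append(x)
        conv, gn = self.latent
        latent = gn(conv(x)).relu()
        x = latent
        skips = list(reversed(enc_feats[:-1])) + [None]
        for (deconv, gn), skip in zip(self.dec, skips):
            x = gn(deconv(x)).relu()
            if skip is not None:
                x = Tensor.concat([x, skip], axis=1)
        return self.flow_head(x), latent


# ---------------------------------------------------------------------------
# Single-file model container
# ---------------------------------------------------------------------------

def save_model(path, config: dict, parameters) -> None:
    """Save model weights + JSON config in one ``.npz`` container."""
    arrays = {f"param_{i:04d}": p.data for i, p in enumerate(parameters)}
    arrays["config_json"] = np.frombuffer(
        json.dumps(config).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path, builders: dict):
    """Rebuild a model from a container written by :func:`save_model`.

    ``builders`` maps the config ``kind`` to a callable(config) -> model.
    """
    with np.load(path) as data:
        config = json.loads(bytes(data["config_json"].tobytes()).decode())
        model = builders[config["kind"]](config)
        params = model.parameters()
        for i, p in enumerate(params):
            p.data = np.array(data[f"param_{i:04d}"], dtype=np.float64)
    return model
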
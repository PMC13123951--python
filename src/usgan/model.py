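"""Switchable CycleGAN networks: one shared generator steered by AdaIN codes,
the AdaIN code generator (ACG), and two patch-level discriminators.

The translation direction is not baked into the generator weights. A small
fully connected ACG maps a direction tag (forward: low→high quality,
backward: high→low) to per-layer channel-wise (shift, scale) statistics;
the generator's residual blocks re-normalize their feature maps to those
statistics (adaptive instance normalization), so a single set of
convolutional weights realizes both mappings. Both directions therefore
share one feature space, which is the architectural argument for structure
preservation: the code modulates channel statistics, it cannot synthesize
new spatial structure on its own.

All networks are plain numpy (see :mod:`usgan.nn`); forward passes are
deterministic given weights, and training-time gradients are accumulated
by explicit backward passes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .images import as_array

CHECKPOINT_FORMAT_VERSION = "usgan-ckpt-1"

FORWARD, BACKWARD = "forward", "backward"


def adain(f: np.ndarray, shift: np.ndarray, scale: np.ndarray,
          eps: float = 1e-5) -> np.ndarray:
    """Adaptive instance normalization of a feature map.

    Per channel c: ``out = scale[c] * (f_c - mean(f_c)) / (std(f_c) + eps)
    + shift[c]`` with the population standard deviation taken over spatial
    positions. Accepts (C,H,W) or (N,C,H,W) feature maps; output shape
    equals input shape.
    """
    f = np.asarray(f, dtype=np.float64)
    squeeze = f.ndim == 3
    if squeeze:
        f = f[None]
    if f.ndim != 4:
        raise ValueError(f"expected (C,H,W) or (N,C,H,W), got shape {f.shape}")
    shift = np.asarray(shift, dtype=np.float64).reshape(-1)
    scale = np.asarray(scale, dtype=np.float64).reshape(-1)
    if shift.size != f.shape[1] or scale.size != f.shape[1]:
        raise ValueError(
            f"code length {shift.size}/{scale.size} does not match "
            f"{f.shape[1]} channels")
    mu = f.mean(axis=(2, 3), keepdims=True)
    u = f - mu
    sigma = np.sqrt((u * u).mean(axis=(2, 3), keepdims=True))
    out = scale[None, :, None, None] * u / (sigma + eps) + shift[None, :, None, None]
    return out[0] if squeeze else out


@dataclass
class AdaINCode:
    """Per-modulated-layer (shift, scale) vectors plus the direction tag."""

    shifts: list[np.ndarray]
    scales: list[np.ndarray]
    direction_tag: str

    def __post_init__(self):
        if self.direction_tag not in (FORWARD, BACKWARD):
            raise ValueError(f"unknown direction tag {self.direction_tag!r}")
        for sc in self.scales:
            if np.any(sc <= 0):
                raise ValueError("AdaIN scale entries must be strictly positive")


class ACG:
    """AdaIN code generator: direction one-hot → all (shift, scale) vectors.

    A two-layer fully connected network. Scales pass through an exponential
    activation so positivity holds by construction; the final layer is
    initialized with small weights and zero bias so initial codes sit near
    (shift 0, scale 1), i.e. the modulated layers start as plain instance
    normalization.
    """

    def __init__(self, n_layers: int, channels: int, hidden: int = 64,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_layers, self.channels = n_layers, channels
        total = n_layers * channels
        self.fc1 = nn.Linear(2, hidden, rng=rng, dtype=dtype)
        self.act = nn.ReLU()
        self.fc2 = nn.Linear(hidden, 2 * total, rng=rng, init_std=0.01, dtype=dtype)
        self.layers = [self.fc1, self.fc2]

    def forward(self, direction_tag: str, with_cache: bool = False):
        if direction_tag not in (FORWARD, BACKWARD):
            raise ValueError(f"unknown direction tag {direction_tag!r}")
        onehot = np.array([[1.0, 0.0]] if direction_tag == FORWARD else [[0.0, 1.0]],
                          dtype=self.fc1.p["W"].dtype)
        h1, c1 = self.fc1.forward(onehot)
        h2, c2 = self.act.forward(h1)
        raw, c3 = self.fc2.forward(h2)
        total = self.n_layers * self.channels
        raw_shift = raw[0, :total]
        raw_scale = raw[0, total:]
        scale_flat = np.exp(raw_scale)
        shifts = [raw_shift[i * self.channels:(i + 1) * self.channels]
                  for i in range(self.n_layers)]
        scales = [scale_flat[i * self.channels:(i + 1) * self.channels]
                  for i in range(self.n_layers)]
        code = AdaINCode(shifts, scales, direction_tag)
        if with_cache:
            return code, (c1, c2, c3, scale_flat)
        return code

    def backward(self, dshifts: list[np.ndarray], dscales: list[np.ndarray],
                 cache) -> None:
        c1, c2, c3, scale_flat = cache
        dshift_flat = np.concatenate(dshifts)
        dscale_flat = np.concatenate(dscales)
        draw = np.concatenate([dshift_flat, dscale_flat * scale_flat])[None, :]
        dh2 = self.fc2.backward(draw.astype(self.fc2.p["W"].dtype), c3)
        dh1 = self.act.backward(dh2, c2)
        self.fc1.backward(dh1, c1)

    def zero_grad(self):
        for ly in self.layers:
            ly.zero_grad()


class Generator:
    """Shared encoder / AdaIN-modulated residual bottleneck / decoder.

    Layout: a 7x7 convolution, two stride-2 downsampling convolutions
    (instance-normalized), ``n_res_blocks`` residual blocks whose
    normalizations are AdaIN layers driven by the code, two nearest-neighbour
    upsampling stages, and a final 7x7 convolution. The final convolution's
    output is added to the input (a global residual connection) before the
    tanh output activation, so an untrained generator is already close to
    the identity and training only has to learn the translation *delta* —
    a deliberate structure-preservation bias.

    Works on tensors in [-1, 1]; :meth:`translate` handles the [0, 1]
    image convention at the I/O boundary.
    """

    def __init__(self, base_channels: int = 32, n_res_blocks: int = 4,
                 eps: float = 1e-5, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        b = base_channels
        self.base_channels, self.n_res_blocks, self.eps = b, n_res_blocks, eps
        self.downsampling_factor = 4
        self.bottleneck_channels = 4 * b
        self.n_adain_layers = 2 * n_res_blocks

        def conv(cin, cout, k, stride=1):
            return nn.Conv2d(cin, cout, k, stride=stride, rng=rng, dtype=dtype)

        self.enc = [
            (conv(1, b, 7), nn.InstanceNorm2d(b, eps, dtype), nn.ReLU()),
            (conv(b, 2 * b, 3, 2), nn.InstanceNorm2d(2 * b, eps, dtype), nn.ReLU()),
            (conv(2 * b, 4 * b, 3, 2), nn.InstanceNorm2d(4 * b, eps, dtype), nn.ReLU()),
        ]
        self.res = []
        for _ in range(n_res_blocks):
            self.res.append((
                conv(4 * b, 4 * b, 3), nn.AdaIN(eps), nn.ReLU(),
                conv(4 * b, 4 * b, 3), nn.AdaIN(eps),
            ))
        self.dec = [
            (nn.UpsampleNearest2(), conv(4 * b, 2 * b, 3),
             nn.InstanceNorm2d(2 * b, eps, dtype), nn.ReLU()),
            (nn.UpsampleNearest2(), conv(2 * b, b, 3),
             nn.InstanceNorm2d(b, eps, dtype), nn.ReLU()),
        ]
        self.out_conv = conv(b, 1, 7)
        self.tanh = nn.Tanh()

        self.layers: list[nn.Layer] = []
        for cv, inorm, _ in self.enc:
            self.layers += [cv, inorm]
        for cv1, _, _, cv2, _ in self.res:
            self.layers += [cv1, cv2]
        for _, cv, inorm, _ in self.dec:
            self.layers += [cv, inorm]
        self.layers.append(self.out_conv)

    # -- core passes ------------------------------------------------------

    def forward(self, x: np.ndarray, code: AdaINCode):
        """x: (N,1,H,W) in [-1,1]; returns (y, caches) with y in (-1,1)."""
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N,1,H,W), got shape {x.shape}")
        f = self.downsampling_factor
        if x.shape[2] % f or x.shape[3] % f:
            raise ValueError(
                f"input spatial dims {x.shape[2]}x{x.shape[3]} must be "
                f"multiples of {f}")
        if len(code.shifts) != self.n_adain_layers:
            raise ValueError(
                f"code has {len(code.shifts)} layers, generator expects "
                f"{self.n_adain_layers}")
        caches = {"enc": [], "res": [], "dec": []}
        h = x
        for cv, inorm, act in self.enc:
            h, c1 = cv.forward(h)
            h, c2 = inorm.forward(h)
            h, c3 = act.forward(h)
            caches["enc"].append((c1, c2, c3))
        k = 0
        for cv1, ad1, act, cv2, ad2 in self.res:
            skip = h
            h1, c1 = cv1.forward(h)
            h2, c2 = ad1.forward(h1, code.shifts[k], code.scales[k])
            h3, c3 = act.forward(h2)
            h4, c4 = cv2.forward(h3)
            h5, c5 = ad2.forward(h4, code.shifts[k + 1], code.scales[k + 1])
            h = skip + h5
            caches["res"].append((c1, c2, c3, c4, c5))
            k += 2
        for up, cv, inorm, act in self.dec:
            h, c0 = up.forward(h)
            h, c1 = cv.forward(h)
            h, c2 = inorm.forward(h)
            h, c3 = act.forward(h)
            caches["dec"].append((c0, c1, c2, c3))
        h, c_out = self.out_conv.forward(h)
        pre = h + x  # global residual
        y, c_tanh = self.tanh.forward(pre)
        caches["out"] = c_out
        caches["tanh"] = c_tanh
        return y, caches

    def backward(self, dy: np.ndarray, caches, accumulate: bool = True):
        """Returns (dx, dshifts, dscales) with code grads in layer order."""
        dpre = self.tanh.backward(dy, caches["tanh"])
        dh = self.out_conv.backward(dpre, caches["out"], accumulate)
        dx_res = dpre  # global residual path
        for (up, cv, inorm, act), (c0, c1, c2, c3) in zip(
                reversed(self.dec), reversed(caches["dec"])):
            dh = act.backward(dh, c3)
            dh = inorm.backward(dh, c2, accumulate)
            dh = cv.backward(dh, c1, accumulate)
            dh = up.backward(dh, c0)
        n_codes = self.n_adain_layers
        dshifts = [None] * n_codes
        dscales = [None] * n_codes
        k = n_codes - 2
        for (cv1, ad1, act, cv2, ad2), (c1, c2, c3, c4, c5) in zip(
                reversed(self.res), reversed(caches["res"])):
            dskip = dh
            dh5 = dh
            dh4, dsh2, dsc2 = ad2.backward(dh5, c5)
            dh3 = cv2.backward(dh4, c4, accumulate)
            dh2 = act.backward(dh3, c3)
            dh1, dsh1, dsc1 = ad1.backward(dh2, c2)
            dh = cv1.backward(dh1, c1, accumulate) + dskip
            dshifts[k], dscales[k] = dsh1, dsc1
            dshifts[k + 1], dscales[k + 1] = dsh2, dsc2
            k -= 2
        for (cv, inorm, act), (c1, c2, c3) in zip(
                reversed(self.enc), reversed(caches["enc"])):
            dh = act.backward(dh, c3)
            dh = inorm.backward(dh, c2, accumulate)
            dh = cv.backward(dh, c1, accumulate)
        return dh + dx_res, dshifts, dscales

    # -- conveniences ------------------------------------------------------

    def translate(self, img, code: AdaINCode) -> np.ndarray:
        """Translate a [0,1] grey image (or batch) in one feed-forward pass."""
        arr = as_array(img) if not (isinstance(img, np.ndarray) and img.ndim == 4) else img
        squeeze = arr.ndim == 2
        if squeeze:
            arr = arr[None, None]
        x = (2.0 * arr - 1.0).astype(self.out_conv.p["W"].dtype)
        y, _ = self.forward(x, code)
        out = np.clip((np.asarray(y, dtype=np.float64) + 1.0) / 2.0, 0.0, 1.0)
        return out[0, 0] if squeeze else out

    def zero_grad(self):
        for ly in self.layers:
            ly.zero_grad()


class Discriminator:
    """Patch-level realness scorer: 4 stride-2 convolutions with progressive
    downsampling, then a stride-1 head; a HxW input yields an (H/16, W/16)
    score grid. Scores are unbounded (least-squares adversarial targets are
    applied in the training loop)."""

    def __init__(self, base_channels: int = 32, n_blocks: int = 4,
                 eps: float = 1e-5, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        b = base_channels
        self.base_channels, self.n_blocks = b, n_blocks
        self.downsampling_factor = 2**n_blocks
        self.blocks = []
        cin = 1
        for i in range(n_blocks):
            cout = min(b * 2**i, 8 * b)
            cv = nn.Conv2d(cin, cout, 4, stride=2, pad=1, rng=rng, dtype=dtype)
            inorm = nn.InstanceNorm2d(cout, eps, dtype) if i > 0 else None
            self.blocks.append((cv, inorm, nn.LeakyReLU(0.2)))
            cin = cout
        self.head = nn.Conv2d(cin, 1, 3, stride=1, pad=1, rng=rng, dtype=dtype)
        self.layers = []
        for cv, inorm, _ in self.blocks:
            self.layers.append(cv)
            if inorm is not None:
                self.layers.append(inorm)
        self.layers.append(self.head)

    def forward(self, x01: np.ndarray):
        """x01: (N,1,H,W) in [0,1]; returns (scores, caches)."""
        h = (2.0 * x01 - 1.0).astype(self.head.p["W"].dtype)
        caches = []
        for cv, inorm, act in self.blocks:
            h, c1 = cv.forward(h)
            c2 = None
            if inorm is not None:
                h, c2 = inorm.forward(h)
            h, c3 = act.forward(h)
            caches.append((c1, c2, c3))
        scores, c_head = self.head.forward(h)
        return scores, (caches, c_head)

    def backward(self, dscores: np.ndarray, cache, accumulate: bool = True):
        caches, c_head = cache
        dh = self.head.backward(dscores, c_head, accumulate)
        for (cv, inorm, act), (c1, c2, c3) in zip(reversed(self.blocks),
                                                  reversed(caches)):
            dh = act.backward(dh, c3)
            if inorm is not None:
                dh = inorm.backward(dh, c2, accumulate)
            dh = cv.backward(dh, c1, accumulate)
        return dh * 2.0  # through the 2x-1 input mapping

    def score(self, img) -> np.ndarray:
        arr = as_array(img)
        scores, _ = self.forward(arr[None, None])
        return np.asarray(scores[0, 0], dtype=np.float64)

    def zero_grad(self):
        for ly in self.layers:
            ly.zero_grad()


@dataclass
class ModelBundle:
    """Generator + ACG + two discriminators with their hyperparameters.

    discriminator A judges the low-quality domain X, discriminator B the
    high-quality domain Y.
    """

    generator: Generator
    acg: ACG
    disc_a: Discriminator
    disc_b: Discriminator
    hyperparams: dict = field(default_factory=dict)

    @classmethod
    def create(cls, base_channels: int = 32, n_res_blocks: int = 4,
               disc_blocks: int = 4, acg_hidden: int = 64,
               epsilon: float = 1e-5, seed: int = 0,
               dtype=np.float32) -> "ModelBundle":
        root = np.random.SeedSequence(seed)
        sg, sa, sda, sdb = (np.random.default_rng(s) for s in root.spawn(4))
        gen = Generator(base_channels, n_res_blocks, epsilon, rng=sg, dtype=dtype)
        acg = ACG(gen.n_adain_layers, gen.bottleneck_channels, acg_hidden,
                  rng=sa, dtype=dtype)
        disc_a = Discriminator(base_channels, disc_blocks, epsilon, rng=sda, dtype=dtype)
        disc_b = Discriminator(base_channels, disc_blocks, epsilon, rng=sdb, dtype=dtype)
        hp = {"base_channels": base_channels, "n_res_blocks": n_res_blocks,
              "disc_blocks": disc_blocks, "acg_hidden": acg_hidden,
              "epsilon": epsilon, "seed": seed,
              "n_adain_layers": gen.n_adain_layers}
        return cls(gen, acg, disc_a, disc_b, hp)

    # -- the user-facing operations ---------------------------------------

    def generate(self, img, direction: str = FORWARD) -> np.ndarray:
        """Translate a [0,1] grey image in a single feed-forward pass."""
        code = self.acg.forward(direction)
        return self.generator.translate(img, code)

    def discriminate(self, img, which: str = "A") -> np.ndarray:
        """Patch-level realness score grid from discriminator A (domain X)
        or B (domain Y)."""
        if which not in ("A", "B"):
            raise ValueError(f"discriminator must be 'A' or 'B', got {which!r}")
        d = self.disc_a if which == "A" else self.disc_b
        return d.score(img)

    # -- checkpointing ------------------------------------------------------

    def _named_layers(self):
        for i, ly in enumerate(self.generator.layers):
            yield f"gen.{i}", ly
        for i, ly in enumerate(self.acg.layers):
            yield f"acg.{i}", ly
        for i, ly in enumerate(self.disc_a.layers):
            yield f"da.{i}", ly
        for i, ly in enumerate(self.disc_b.layers):
            yield f"db.{i}", ly

    def save(self, path, extra_arrays: dict | None = None) -> None:
        arrays = {}
        for name, ly in self._named_layers():
            for k, v in ly.p.items():
                arrays[f"{name}.{k}"] = v
        if extra_arrays:
            for k, v in extra_arrays.items():
                arrays[f"extra.{k}"] = np.asarray(v)
        meta = dict(self.hyperparams)
        meta["format_version"] = CHECKPOINT_FORMAT_VERSION
        np.savez(path, __meta__=np.bytes_(json.dumps(meta, sort_keys=True)),
                 **arrays)

    @staticmethod
    def read_extra(path) -> dict:
        """Read back any extra arrays stored next to the weights."""
        out = {}
        with np.load(path) as data:
            for k in data.files:
                if k.startswith("extra."):
                    out[k[len("extra."):]] = data[k].copy()
        return out

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint format {meta.get('format_version')!r}")
            bundle = cls.create(
                base_channels=meta["base_channels"],
                n_res_blocks=meta["n_res_blocks"],
                disc_blocks=meta["disc_blocks"],
                acg_hidden=meta["acg_hidden"],
                epsilon=meta["epsilon"],
                seed=meta["seed"])
            for name, ly in bundle._named_layers():
                for k in ly.p:
                    ly.p[k] = data[f"{name}.{k}"].copy()
                ly.zero_grad()
        bundle.hyperparams = {k: v for k, v in meta.items() if k != "format_version"}
        return bundle

    def all_layers(self):
        return [ly for _, ly in self._named_layers()]

    def zero_grad(self):
        for ly in self.all_layers():
            ly.zero_grad()
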
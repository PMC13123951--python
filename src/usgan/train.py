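"""Two-cycle adversarial training for the switchable generator.

One training step runs the forward cycle (X → Y via the forward code, back
to X via the backward code), the backward cycle (the mirror image), identity
passes (each domain translated "into itself" with the code that targets it),
discriminator updates for both domains, and a generator+ACG update with

    total_G = l_adv + lambda_cycle * l_cycle + lambda_identity * l_iden.

The generator is a single shared network: all six generator applications in
a step accumulate gradients into the same weights, and the two directions
differ only through the AdaIN codes.

The top-level API follows the model/results convention: build a
:class:`SwitchableCycleGAN` from two unpaired image sets, call ``fit()``,
and get a :class:`TranslationResults` holding the trained weights, the loss
history and translation/summary/plotting helpers. The plain functions
(:func:`train_step`, :func:`fit`, the losses) remain available for direct
use.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .images import as_array, load_image, preprocess
from .model import ACG, BACKWARD, FORWARD, Generator, ModelBundle

logger = logging.getLogger("usgan")

LS, XENT = "least-squares", "cross-entropy"

HISTORY_COLUMNS = ("step", "loss_adv_G", "loss_adv_D_A", "loss_adv_D_B",
                   "loss_cycle", "loss_identity", "total_G")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the adversarial training loop.

    Defaults are desk-scale (small crops, CPU-friendly); ``paper_scale()``
    returns the 384-crop convention used for full-size training.
    """

    lambda_cycle: float = 10.0
    lambda_identity: float = 5.0
    learning_rate: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    epochs: int = 1
    batch_size: int = 1
    crop_size: int = 128
    resize_to: int = 128
    seed: int = 0
    adversarial_form: str = LS
    steps_per_epoch: int | None = None

    def __post_init__(self):
        if self.lambda_cycle < 0 or self.lambda_identity < 0:
            raise ValueError("loss weights must be non-negative")
        if self.crop_size > self.resize_to:
            raise ValueError("crop_size must not exceed resize_to")
        if self.adversarial_form not in (LS, XENT):
            raise ValueError(f"unknown adversarial form {self.adversarial_form!r}")

    @classmethod
    def paper_scale(cls, **overrides) -> "TrainConfig":
        kw = dict(crop_size=384, resize_to=400)
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class LossRecord:
    step: int
    loss_adv_G: float
    loss_adv_D_A: float
    loss_adv_D_B: float
    loss_cycle: float
    loss_identity: float
    total_G: float

    def __post_init__(self):
        for name, value in asdict(self).items():
            if not np.isfinite(value):
                raise RuntimeError(f"non-finite training loss: {name} = {value}")


# ---------------------------------------------------------------------------
# losses


def cycle_loss(original, reconstructed) -> float:
    """Mean absolute pixel difference between an image and its
    translate-then-back-translate reconstruction."""
    a, b = np.asarray(original, dtype=np.float64), np.asarray(reconstructed, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).mean())


def identity_loss(target_domain_img, translated_self) -> float:
    """Mean absolute difference between an in-target-domain image and the
    generator's attempt to translate it into its own domain."""
    return cycle_loss(target_domain_img, translated_self)


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def adversarial_losses(real_scores, fake_scores, role: str, form: str = LS) -> float:
    """Adversarial objective value for one player.

    Least-squares form (default): the discriminator minimizes
    mean[(real-1)^2] + mean[fake^2]; the generator minimizes
    mean[(fake-1)^2]. Cross-entropy form treats scores as logits.
    """
    if role not in ("generator", "discriminator"):
        raise ValueError(f"unknown role {role!r}")
    if form not in (LS, XENT):
        raise ValueError(f"unknown adversarial form {form!r}")
    fake = np.asarray(fake_scores, dtype=np.float64)
    if not np.all(np.isfinite(fake)):
        raise ValueError("non-finite fake scores")
    if role == "generator":
        if form == LS:
            return float(((fake - 1.0) ** 2).mean())
        return float(_softplus(-fake).mean())
    real = np.asarray(real_scores, dtype=np.float64)
    if not np.all(np.isfinite(real)):
        raise ValueError("non-finite real scores")
    if form == LS:
        return float(((real - 1.0) ** 2).mean() + (fake**2).mean())
    return float(_softplus(-real).mean() + _softplus(fake).mean())


def _adv_grad_generator(fake_scores: np.ndarray, form: str) -> np.ndarray:
    n = fake_scores.size
    if form == LS:
        return 2.0 * (fake_scores - 1.0) / n
    return (_sigmoid(fake_scores) - 1.0) / n


def _adv_grads_discriminator(real_scores, fake_scores, form: str):
    nr, nf = real_scores.size, fake_scores.size
    if form == LS:
        return 2.0 * (real_scores - 1.0) / nr, 2.0 * fake_scores / nf
    return -_sigmoid(-real_scores) / nr, _sigmoid(fake_scores) / nf


# ---------------------------------------------------------------------------
# generator application with [0,1] <-> [-1,1] boundary handled


def _g_apply(gen: Generator, x01: np.ndarray, code):
    x = (2.0 * x01 - 1.0).astype(np.float32)
    y, caches = gen.forward(x, code)
    return (np.asarray(y, dtype=np.float64) + 1.0) / 2.0, caches


def _g_backward(gen: Generator, dy01: np.ndarray, caches):
    dx, dshifts, dscales = gen.backward((dy01 * 0.5).astype(np.float32), caches)
    return np.asarray(dx, dtype=np.float64) * 2.0, dshifts, dscales


def _l1_grad(a: np.ndarray, b: np.ndarray, weight: float) -> np.ndarray:
    """Subgradient of weight * mean|a - b| with respect to a."""
    return weight * np.sign(a - b) / a.size


class _CodeGradAccumulator:
    def __init__(self, n_layers: int):
        self.dshifts = [None] * n_layers
        self.dscales = [None] * n_layers

    def add(self, dshifts, dscales):
        for i, (dsh, dsc) in enumerate(zip(dshifts, dscales)):
            self.dshifts[i] = dsh if self.dshifts[i] is None else self.dshifts[i] + dsh
            self.dscales[i] = dsc if self.dscales[i] is None else self.dscales[i] + dsc


def _as_batch(batch) -> np.ndarray:
    """Coerce a list of 2-D images or an array to (N,1,H,W) float64 in [0,1]."""
    if isinstance(batch, np.ndarray) and batch.ndim == 4:
        return np.asarray(batch, dtype=np.float64)
    imgs = [as_array(b) for b in batch]
    return np.stack(imgs)[:, None, :, :].astype(np.float64)


def make_optimizers(bundle: ModelBundle, cfg: TrainConfig):
    """Adam optimizers: one over generator+ACG, one per discriminator."""
    opt_g = nn.Adam(bundle.generator.layers + bundle.acg.layers,
                    lr=cfg.learning_rate, betas=cfg.betas)
    opt_da = nn.Adam(bundle.disc_a.layers, lr=cfg.learning_rate, betas=cfg.betas)
    opt_db = nn.Adam(bundle.disc_b.layers, lr=cfg.learning_rate, betas=cfg.betas)
    return opt_g, opt_da, opt_db


def train_step(batch_X, batch_Y, bundle: ModelBundle, cfg: TrainConfig,
               optimizers=None, step: int = 0) -> LossRecord:
    """One simultaneous update of generator+ACG and both discriminators.

    ``batch_X`` / ``batch_Y`` are unpaired [0,1] image batches. Model
    parameters are updated in place; a finite :class:`LossRecord` is
    returned (non-finite losses raise, naming the offending term).
    """
    x = _as_batch(batch_X)
    y = _as_batch(batch_Y)
    gen, acg = bundle.generator, bundle.acg
    d_a, d_b = bundle.disc_a, bundle.disc_b
    if optimizers is None:
        optimizers = make_optimizers(bundle, cfg)
    opt_g, opt_da, opt_db = optimizers
    form = cfg.adversarial_form

    # ---- generator + ACG update ------------------------------------------
    gen.zero_grad()
    acg.zero_grad()
    code_f, cache_af = acg.forward(FORWARD, with_cache=True)
    code_b, cache_ab = acg.forward(BACKWARD, with_cache=True)

    fake_y, c_f1 = _g_apply(gen, x, code_f)      # X -> Y
    fake_x, c_b1 = _g_apply(gen, y, code_b)      # Y -> X
    rec_x, c_b2 = _g_apply(gen, fake_y, code_b)  # X -> Y -> X
    rec_y, c_f2 = _g_apply(gen, fake_x, code_f)  # Y -> X -> Y
    idt_y, c_f3 = _g_apply(gen, y, code_f)       # Y -> Y (identity pass)
    idt_x, c_b3 = _g_apply(gen, x, code_b)       # X -> X (identity pass)

    s_fake_y, c_db = d_b.forward(fake_y)
    s_fake_x, c_da = d_a.forward(fake_x)
    s_fake_y = np.asarray(s_fake_y, dtype=np.float64)
    s_fake_x = np.asarray(s_fake_x, dtype=np.float64)

    l_adv_g = (adversarial_losses(None, s_fake_y, "generator", form)
               + adversarial_losses(None, s_fake_x, "generator", form))
    l_cycle = cycle_loss(x, rec_x) + cycle_loss(y, rec_y)
    l_iden = identity_loss(y, idt_y) + identity_loss(x, idt_x)
    total_g = l_adv_g + cfg.lambda_cycle * l_cycle + cfg.lambda_identity * l_iden

    acc_f = _CodeGradAccumulator(gen.n_adain_layers)
    acc_b = _CodeGradAccumulator(gen.n_adain_layers)

    # adversarial gradients flow into the fakes through frozen discriminators
    d_fake_y = d_b.backward(_adv_grad_generator(s_fake_y, form).astype(np.float32),
                            c_db, accumulate=False).astype(np.float64)
    d_fake_x = d_a.backward(_adv_grad_generator(s_fake_x, form).astype(np.float32),
                            c_da, accumulate=False).astype(np.float64)

    # cycle reconstructions: back-prop through the second generator pass,
    # adding the resulting gradient to the fakes
    g_rec_x, dsh, dsc = _g_backward(gen, _l1_grad(rec_x, x, cfg.lambda_cycle), c_b2)
    acc_b.add(dsh, dsc)
    d_fake_y = d_fake_y + g_rec_x
    g_rec_y, dsh, dsc = _g_backward(gen, _l1_grad(rec_y, y, cfg.lambda_cycle), c_f2)
    acc_f.add(dsh, dsc)
    d_fake_x = d_fake_x + g_rec_y

    # first generator passes
    _, dsh, dsc = _g_backward(gen, d_fake_y, c_f1)
    acc_f.add(dsh, dsc)
    _, dsh, dsc = _g_backward(gen, d_fake_x, c_b1)
    acc_b.add(dsh, dsc)

    # identity passes
    if cfg.lambda_identity > 0:
        _, dsh, dsc = _g_backward(gen, _l1_grad(idt_y, y, cfg.lambda_identity), c_f3)
        acc_f.add(dsh, dsc)
        _, dsh, dsc = _g_backward(gen, _l1_grad(idt_x, x, cfg.lambda_identity), c_b3)
        acc_b.add(dsh, dsc)

    acg.backward(acc_f.dshifts, acc_f.dscales, cache_af)
    acg.backward(acc_b.dshifts, acc_b.dscales, cache_ab)
    opt_g.step()

    # ---- discriminator updates (on pre-update fakes, detached) ------------
    def update_disc(disc, opt, real, fake):
        disc.zero_grad()
        s_real, c_real = disc.forward(real)
        s_fake, c_fake = disc.forward(fake)
        s_real = np.asarray(s_real, dtype=np.float64)
        s_fake = np.asarray(s_fake, dtype=np.float64)
        loss = adversarial_losses(s_real, s_fake, "discriminator", form)
        g_real, g_fake = _adv_grads_discriminator(s_real, s_fake, form)
        disc.backward(g_real.astype(np.float32), c_real)
        disc.backward(g_fake.astype(np.float32), c_fake)
        opt.step()
        return loss

    l_d_a = update_disc(d_a, opt_da, x, fake_x)
    l_d_b = update_disc(d_b, opt_db, y, fake_y)

    return LossRecord(step=step, loss_adv_G=float(l_adv_g),
                      loss_adv_D_A=float(l_d_a), loss_adv_D_B=float(l_d_b),
                      loss_cycle=float(l_cycle), loss_identity=float(l_iden),
                      total_G=float(total_g))


# ---------------------------------------------------------------------------
# data handling and the fit loop


def _load_folder(folder) -> list[np.ndarray]:
    folder = Path(folder)
    paths = sorted(p for p in folder.iterdir()
                   if p.suffix.lower() in (".png", ".dcm", ".dicom"))
    images = []
    for p in paths:
        try:
            images.append(load_image(p).values)
        except Exception as exc:  # unreadable file: skip with a warning
            logger.warning("skipping unreadable image %s: %s", p, exc)
    if not images:
        raise ValueError(f"no readable images in {folder}")
    return images


def _coerce_images(source) -> list[np.ndarray]:
    if isinstance(source, (str, Path)):
        return _load_folder(source)
    return [as_array(img) for img in source]


def _sample_batch(images, cfg: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    batch = []
    for _ in range(cfg.batch_size):
        img = images[int(rng.integers(len(images)))]
        crop_seed = int(rng.integers(2**31))
        batch.append(preprocess(img, cfg.resize_to, cfg.crop_size, seed=crop_seed))
    return np.stack(batch)[:, None, :, :]


def fit(dataset_dirs, cfg: TrainConfig, bundle: ModelBundle | None = None,
        checkpoint_dir=None, **bundle_kwargs):
    """Train on unpaired folders (or image lists); returns (bundle, history).

    ``dataset_dirs`` is an (X, Y) pair of folder paths or image sequences.
    Batches are seeded-shuffled and augmented by short-side resize plus
    random crop; a checkpoint is written per epoch when ``checkpoint_dir``
    is given. The full loss history (one :class:`LossRecord` per step) is
    returned alongside the trained bundle.
    """
    x_source, y_source = dataset_dirs
    x_images = _coerce_images(x_source)
    y_images = _coerce_images(y_source)
    if bundle is None:
        bundle = ModelBundle.create(seed=cfg.seed, **bundle_kwargs)
    optimizers = make_optimizers(bundle, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    steps_per_epoch = cfg.steps_per_epoch
    if steps_per_epoch is None:
        steps_per_epoch = max(1, max(len(x_images), len(y_images)) // cfg.batch_size)
    history: list[LossRecord] = []
    step = 0
    for epoch in range(cfg.epochs):
        for _ in range(steps_per_epoch):
            bx = _sample_batch(x_images, cfg, rng)
            by = _sample_batch(y_images, cfg, rng)
            rec = train_step(bx, by, bundle, cfg, optimizers, step=step)
            history.append(rec)
            step += 1
        logger.info("epoch %d/%d: total_G=%.4f cycle=%.4f",
                    epoch + 1, cfg.epochs, history[-1].total_G,
                    history[-1].loss_cycle)
        if checkpoint_dir is not None:
            ckpt_dir = Path(checkpoint_dir)
            ckpt_dir.mkdir(parents=True, exist_ok=True)
            bundle.save(ckpt_dir / f"epoch_{epoch + 1:04d}.npz",
                        extra_arrays={"history": history_to_array(history)})
    return bundle, history


def history_to_array(history: list[LossRecord]) -> np.ndarray:
    return np.array([[getattr(r, c) for c in HISTORY_COLUMNS] for r in history],
                    dtype=np.float64)


def history_to_frame(history) -> pd.DataFrame:
    if isinstance(history, np.ndarray):
        df = pd.DataFrame(history, columns=list(HISTORY_COLUMNS))
    else:
        df = pd.DataFrame([asdict(r) for r in history], columns=list(HISTORY_COLUMNS))
    df["step"] = df["step"].astype(int)
    return df


def write_history_csv(history, path) -> None:
    history_to_frame(history).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model / results objects


class SwitchableCycleGAN:
    """Unpaired image-quality translation model.

    Built from two unpaired image sets — ``x_images`` (low quality) and
    ``y_images`` (high quality), each a folder path or a sequence of [0,1]
    arrays — plus a :class:`TrainConfig` and architecture keywords
    (``base_channels``, ``n_res_blocks``, ``disc_blocks``, ``acg_hidden``,
    ``epsilon``). ``fit()`` trains the networks and returns a
    :class:`TranslationResults`.
    """

    def __init__(self, x_images, y_images, config: TrainConfig | None = None,
                 **bundle_kwargs):
        self.x_images = _coerce_images(x_images)
        self.y_images = _coerce_images(y_images)
        self.config = config if config is not None else TrainConfig()
        self.bundle_kwargs = bundle_kwargs

    @classmethod
    def from_folders(cls, x_dir, y_dir, config: TrainConfig | None = None,
                     **bundle_kwargs) -> "SwitchableCycleGAN":
        return cls(x_dir, y_dir, config, **bundle_kwargs)

    def fit(self, checkpoint_dir=None) -> "TranslationResults":
        bundle, history = fit((self.x_images, self.y_images), self.config,
                              checkpoint_dir=checkpoint_dir, **self.bundle_kwargs)
        return TranslationResults(bundle, history_to_array(history), self.config)


class TranslationResults:
    """Trained weights plus the loss history, with translation helpers."""

    def __init__(self, bundle: ModelBundle, history: np.ndarray,
                 config: TrainConfig | None = None):
        self.bundle = bundle
        self.history = np.asarray(history, dtype=np.float64).reshape(-1, len(HISTORY_COLUMNS))
        self.config = config

    @property
    def history_frame(self) -> pd.DataFrame:
        return history_to_frame(self.history)

    def translate(self, img, direction: str = FORWARD):
        """Translate one [0,1] image (or a list) in a feed-forward pass."""
        if isinstance(img, (list, tuple)):
            return [self.bundle.generate(im, direction) for im in img]
        return self.bundle.generate(img, direction)

    def summary(self) -> str:
        df = self.history_frame
        hp = self.bundle.hyperparams
        lines = ["Switchable CycleGAN — training summary",
                 "=" * 46]
        lines.append(f"{'steps':<28}{len(df):>16}")
        for key in ("base_channels", "n_res_blocks", "disc_blocks", "epsilon"):
            if key in hp:
                lines.append(f"{key:<28}{hp[key]:>16}")
        if self.config is not None:
            lines.append(f"{'lambda_cycle':<28}{self.config.lambda_cycle:>16}")
            lines.append(f"{'lambda_identity':<28}{self.config.lambda_identity:>16}")
            lines.append(f"{'learning_rate':<28}{self.config.learning_rate:>16}")
        if len(df):
            tenth = max(1, len(df) // 10)
            lines.append("-" * 46)
            for col in ("loss_cycle", "loss_identity", "loss_adv_G", "total_G"):
                first = float(df[col].iloc[:tenth].median())
                last = float(df[col].iloc[-tenth:].median())
                lines.append(f"{col + ' (median first/last 10%)':<34}"
                             f"{first:>10.4f} -> {last:.4f}")
        return "\n".join(lines)

    def plot_history(self, path=None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.history_frame
        fig, ax = plt.subplots(figsize=(7, 4))
        for col in ("loss_cycle", "loss_identity", "loss_adv_G",
                    "loss_adv_D_A", "loss_adv_D_B"):
            ax.plot(df["step"], df[col], label=col, linewidth=1)
        ax.set_xlabel("step")
        ax.set_ylabel("loss")
        ax.legend(fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def save(self, path) -> None:
        self.bundle.save(path, extra_arrays={"history": self.history})

    @classmethod
    def load(cls, path) -> "TranslationResults":
        bundle = ModelBundle.load(path)
        extra = ModelBundle.read_extra(path)
        history = extra.get("history", np.empty((0, len(HISTORY_COLUMNS))))
        return cls(bundle, history)
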
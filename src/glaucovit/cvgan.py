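"""Conditional GAN with a reconstruction path for class rebalancing.

The network has three parts: an encoder ``E`` that maps an image to a class
estimate and a latent code, a generator ``G`` that decodes (latent, class)
back to an image, and a Wasserstein-style discriminator ``D`` with an
unbounded realness score ``Ds`` and an auxiliary five-way class head ``Dd``.
Training couples a critic objective with gradient penalty (weight
``lambda1``), an auxiliary-classifier cross-entropy, an L1 reconstruction
term (weight ``lambda5``) that makes ``G(E(x), y)`` reconstruct ``x``, and a
class-consistency reward ``lambda4 * log p(Dd(x_gen) = y)``.  After
training, class-conditional sampling from a standard-normal latent prior
enlarges the under-represented classes of the training set.

The discriminator minimizes

    L_D = E[Ds(x_gen)] - E[Ds(x)] + L_GP + lambda2 * L_CE

(by default with the auxiliary term ADDED, the AC-GAN convention that
trains the class head toward the true labels; the subtracted composition is
what :func:`discriminator_loss` transcribes and is selectable with
``aux_sign_convention="as_printed"``), and the encoder+generator pair
maximizes

    L_EG = E[Ds(x_gen)] + lambda4 * log p(Dd(x_gen)=y)
           - lambda5 * L1(x, x_gen) - L_CE .

Notes on conventions: the auxiliary cross-entropy is the standard
categorical cross-entropy against the true class (the AC-GAN convention);
the printed entropy-of-softmax variant is kept as a diagnostic monitor
(:func:`entropy_monitor`).  ``lambda3`` is carried in :class:`LossWeights`
but appears in no loss composition and is unused by default.  The critic
contains no batch normalization, as the gradient-penalty formulation
requires a per-sample critic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .labels import N_CLASSES, ClassLabel
from .nn import Tensor
from .phantom import LabeledImage


@dataclass(frozen=True)
class LossWeights:
    """Relative loss weights; lambda1 scales the gradient penalty."""

    lam1: float = 10.0
    lam2: float = 1.0
    lam3: float = 1.0  # declared but not used by any loss composition
    lam4: float = 1.0
    lam5: float = 1.0

    def __post_init__(self) -> None:
        if min(self.lam1, self.lam2, self.lam3, self.lam4, self.lam5) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class CVGANConfig:
    image_size: int = 32  # power of two, >= 8
    latent_dim: int = 128
    base_channels: int = 32
    n_critic: int = 5
    batch_size: int = 16
    lr: float = 1e-4
    betas: tuple[float, float] = (0.5, 0.9)
    weights: LossWeights = field(default_factory=LossWeights)
    class_term_mode: str = "log_prob"  # or "raw_prob"
    # Sign of the auxiliary class term inside the minimized critic objective.
    # "acgan" (default) trains the class head toward the true labels, which
    # is what makes conditional generation converge; "as_printed" keeps the
    # subtracted form of the published composition (see discriminator_loss).
    aux_sign_convention: str = "acgan"
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.image_size
        if n < 8 or n & (n - 1):
            raise ValueError("image_size must be a power of two >= 8")
        if self.class_term_mode not in ("log_prob", "raw_prob"):
            raise ValueError("class_term_mode must be 'log_prob' or 'raw_prob'")
        if self.aux_sign_convention not in ("acgan", "as_printed"):
            raise ValueError("aux_sign_convention must be 'acgan' or 'as_printed'")


def tiny_config(seed: int = 0) -> CVGANConfig:
    """Desk-scale configuration used for CPU-sized experiments."""
    return CVGANConfig(
        image_size=16, latent_dim=16, base_channels=12, n_critic=1, batch_size=8, seed=seed
    )


@dataclass
class EncoderOutput:
    class_probs: np.ndarray  # (5,) softmax, sums to 1
    latent: np.ndarray  # (L,)


@dataclass
class DiscriminatorOutput:
    realness: Tensor  # (B, 1) unbounded critic score
    class_logits: Tensor  # (B, 5)


class Encoder(nn.Module):
    def __init__(self, cfg: CVGANConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.stem = nn.Conv2d(3, c, 1, rng)
        downs = []
        bns = []
        size = cfg.image_size
        while size > 4:
            downs.append(nn.Conv2d(c, 2 * c, 3, rng, stride=2))
            bns.append(nn.BatchNorm2d(c))
            c *= 2
            size //= 2
        self.downs = downs
        self.bns = bns
        self.mix_bn = nn.BatchNorm2d(c)
        self.mix = nn.Conv2d(c, c, 1, rng)
        self.head = nn.Linear(c * 16, N_CLASSES + cfg.latent_dim, rng)
        self.latent_dim = cfg.latent_dim

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.stem(x)
        for conv, bn in zip(self.downs, self.bns):
            h = conv(nn.relu(bn(h)))
        h = self.mix(nn.relu(self.mix_bn(h)))
        b = x.shape[0]
        out = self.head(nn.reshape(h, (b, -1)))
        logits = nn.slice_op(out, (slice(None), slice(0, N_CLASSES)))
        z = nn.slice_op(out, (slice(None), slice(N_CLASSES, None)))
        return logits, z


class Generator(nn.Module):
    def __init__(self, cfg: CVGANConfig, rng: np.random.Generator):
        n_up = int(math.log2(cfg.image_size // 4))
        c = cfg.base_channels * (2**n_up)
        self.c0 = c
        self.fc = nn.Linear(cfg.latent_dim + N_CLASSES, c * 16, rng)
        ups, bns = [], []
        for _ in range(n_up):
            ups.append(nn.Conv2d(c, c // 2, 3, rng))
            bns.append(nn.BatchNorm2d(c))
            c //= 2
        self.ups = ups
        self.bns = bns
        self.mix_bn = nn.BatchNorm2d(c)
        self.mix = nn.Conv2d(c, c, 1, rng)
        self.to_rgb = nn.Conv2d(c, 3, 3, rng)

    def __call__(self, z: Tensor, onehot: Tensor) -> Tensor:
        h = self.fc(nn.concat([z, onehot], axis=1))
        h = nn.reshape(h, (z.shape[0], self.c0, 4, 4))
        for conv, bn in zip(self.ups, self.bns):
            h = conv(nn.upsample2x(nn.relu(bn(h))))
        h = self.mix(nn.relu(self.mix_bn(h)))
        return nn.tanh(self.to_rgb(h))


class Discriminator(nn.Module):
    """Critic + auxiliary class head; normalization-free for the penalty."""

    def __init__(self, cfg: CVGANConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.stem = nn.Conv2d(3, c, 3, rng)
        downs = []
        size = cfg.image_size
        while size > 4:
            downs.append(nn.Conv2d(c, 2 * c, 3, rng, stride=2))
            c *= 2
            size //= 2
        self.downs = downs
        self.head = nn.Linear(c * 16, 1 + N_CLASSES, rng)

    def __call__(self, x: Tensor) -> DiscriminatorOutput:
        h = self.stem(x)
        for conv in self.downs:
            h = conv(nn.leaky_relu(h))
        out = self.head(nn.reshape(nn.leaky_relu(h), (x.shape[0], -1)))
        return DiscriminatorOutput(
            realness=nn.slice_op(out, (slice(None), slice(0, 1))),
            class_logits=nn.slice_op(out, (slice(None), slice(1, None))),
        )


# -- loss system ---------------------------------------------------------

def interpolate_gp_sample(x, x_gen, eps: float):
    """Elementwise convex combination ``eps * x + (1 - eps) * x_gen``."""
    if not 0.0 <= eps <= 1.0:
        raise ValueError("interpolation factor must lie in [0, 1]")
    return eps * x + (1.0 - eps) * x_gen


def gradient_penalty(critic, x_hat: Tensor, lam1: float) -> Tensor:
    """``lam1 * E[(||grad_x Ds(x_hat)||_2 - 1)^2]``; differentiable in the
    critic parameters via double backprop."""
    if not x_hat.requires_grad:
        raise ValueError("x_hat must require grad for the penalty")
    out = critic(x_hat)
    ds = out.realness if isinstance(out, DiscriminatorOutput) else out
    g = nn.grad(nn.tsum(ds), [x_hat])[0]
    if not np.all(np.isfinite(g.data)):
        raise FloatingPointError("non-finite critic gradient at the interpolate")
    b = x_hat.shape[0]
    flat = nn.reshape(g, (b, -1))
    norms = nn.sqrt(nn.tsum(nn.mul(flat, flat), axis=1))
    return lam1 * nn.tmean(nn.power(norms - 1.0, 2.0))


def aux_class_loss(class_logits, true_class):
    """Categorical cross-entropy of softmax(logits) against the true class."""
    logits = class_logits if isinstance(class_logits, Tensor) else Tensor(np.atleast_2d(class_logits))
    if logits.ndim == 1:
        logits = nn.reshape(logits, (1, -1))
    if logits.shape[-1] != N_CLASSES:
        raise ValueError(f"expected {N_CLASSES} class logits")
    codes = np.atleast_1d(np.asarray(
        [true_class.code] if isinstance(true_class, ClassLabel) else true_class, dtype=np.int64
    ))
    if codes.min() < 0 or codes.max() >= N_CLASSES:
        raise ValueError("invalid class code")
    lp = nn.log_softmax(logits, axis=-1)
    picked = nn.take_patches(
        nn.reshape(lp, (1, 1) + lp.shape), np.arange(codes.size), codes
    )
    return -nn.tmean(picked)


def entropy_monitor(class_logits) -> float:
    """Diagnostic: entropy of the softmax (mean over the batch)."""
    logits = np.atleast_2d(np.asarray(
        class_logits.data if isinstance(class_logits, Tensor) else class_logits, dtype=np.float64
    ))
    z = logits - logits.max(axis=-1, keepdims=True)
    p = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)
    return float(np.mean(-(p * np.log(np.clip(p, 1e-300, None))).sum(axis=-1)))


def discriminator_loss(ds_fake, ds_real, gp, lcel, weights: LossWeights):
    """Critic objective: ``E[Ds(fake)] - E[Ds(real)] + GP - lambda2 * LCE``."""
    return (ds_fake - ds_real) + gp - weights.lam2 * lcel


def encoder_generator_loss(ds_fake, class_logprob_fake, l1_recon, lcel, weights: LossWeights):
    """Encoder+generator objective (to be maximized):
    ``E[Ds(fake)] + lambda4 * class_term - lambda5 * L1 - LCE``."""
    return ds_fake + weights.lam4 * class_logprob_fake - weights.lam5 * l1_recon - lcel


def total_objective(led, ldc):
    """Monitoring sum of the two objectives."""
    return led + ldc


# -- training state ------------------------------------------------------

CHECKPOINT_VERSION = 1


class CVGANState:
    """Bundles E/G/D, their optimizers, loss weights and the step counter."""

    def __init__(self, cfg: CVGANConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = Encoder(cfg, rng)
        self.generator = Generator(cfg, rng)
        self.discriminator = Discriminator(cfg, rng)
        self.opt_d = nn.Adam(self.discriminator.parameters(), lr=cfg.lr, betas=cfg.betas)
        self.opt_eg = nn.Adam(
            self.encoder.parameters() + self.generator.parameters(), lr=cfg.lr, betas=cfg.betas
        )
        self.rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
        self.step = 0

    # -- preprocessing ---------------------------------------------------
    @staticmethod
    def to_model_range(pixels: np.ndarray) -> np.ndarray:
        """uint8 HxWx3 -> float (3, H, W) in [-1, 1]."""
        return (pixels.astype(np.float64).transpose(2, 0, 1) / 127.5) - 1.0

    @staticmethod
    def to_uint8(img: np.ndarray) -> np.ndarray:
        """(3, H, W) in [-1, 1] -> uint8 HxWx3."""
        arr = np.clip((img + 1.0) * 127.5, 0, 255)
        return np.rint(arr).astype(np.uint8).transpose(1, 2, 0)

    def _set_eval(self) -> None:
        for m in (self.encoder, self.generator, self.discriminator):
            m.set_training(False)

    def _set_train(self) -> None:
        for m in (self.encoder, self.generator, self.discriminator):
            m.set_training(True)

    # -- public operations ----------------------------------------------
    def encode(self, pixels: np.ndarray) -> EncoderOutput:
        """Deterministic (eval-mode) encoding of one uint8 image."""
        if pixels.shape[0] != self.cfg.image_size or pixels.shape[1] != self.cfg.image_size:
            raise ValueError("image resolution does not match the model")
        self._set_eval()
        x = Tensor(self.to_model_range(pixels)[None])
        logits, z = self.encoder(x)
        probs = nn.softmax(logits, axis=-1).data[0]
        return EncoderOutput(class_probs=probs, latent=z.data[0])

    def generate(self, z: np.ndarray, label: ClassLabel) -> np.ndarray:
        """Decode one latent under a class condition; output in [-1, 1]."""
        if not np.all(np.isfinite(z)):
            raise ValueError("latent must be finite")
        if not isinstance(label, ClassLabel):
            raise ValueError("label must be a ClassLabel")
        self._set_eval()
        onehot = np.zeros((1, N_CLASSES))
        onehot[0, label.code] = 1.0
        out = self.generator(Tensor(z[None]), Tensor(onehot))
        return out.data[0]

    def train_step(self, images: np.ndarray, codes: np.ndarray) -> dict[str, float]:
        """``n_critic`` critic updates then one joint encoder+generator
        update; raises on non-finite losses."""
        self._set_train()
        cfg = self.cfg
        w = cfg.weights
        x = Tensor(images)
        onehot = np.zeros((codes.size, N_CLASSES))
        onehot[np.arange(codes.size), codes] = 1.0
        oh = Tensor(onehot)
        record: dict[str, float] = {}

        for _ in range(cfg.n_critic):
            _, z = self.encoder(x)
            x_gen = Tensor(self.generator(z.detach(), oh).data)  # detached fake
            d_real = self.discriminator(x)
            d_fake = self.discriminator(x_gen)
            eps = self.rng.random((codes.size, 1, 1, 1))
            x_hat = Tensor(eps * x.data + (1.0 - eps) * x_gen.data, requires_grad=True)
            gp = gradient_penalty(self.discriminator, x_hat, w.lam1)
            lcel_d = aux_class_loss(d_real.class_logits, codes)
            # The AC-GAN convention adds the auxiliary term to the minimized
            # objective (training the class head); the literal published
            # composition subtracts it, which anti-trains that head.
            signed_lcel = lcel_d if cfg.aux_sign_convention == "as_printed" else -lcel_d
            ldc = discriminator_loss(
                nn.tmean(d_fake.realness), nn.tmean(d_real.realness), gp, signed_lcel, w
            )
            self.opt_d.zero_grad()
            nn.backward(ldc, self.opt_d.params)
            self.opt_d.step()
            record["loss_d"] = ldc.item()
            record["gp"] = gp.item()

        e_logits, z = self.encoder(x)
        x_gen = self.generator(z, oh)
        d_fake = self.discriminator(x_gen)
        lp = nn.log_softmax(d_fake.class_logits, axis=-1)
        picked = nn.take_patches(nn.reshape(lp, (1, 1) + lp.shape), np.arange(codes.size), codes)
        class_term = nn.tmean(picked if cfg.class_term_mode == "log_prob" else nn.exp(picked))
        l1 = nn.tmean(nn.tabs(x - x_gen))
        lcel_e = aux_class_loss(e_logits, codes)
        led = encoder_generator_loss(nn.tmean(d_fake.realness), class_term, l1, lcel_e, w)
        self.opt_eg.zero_grad()
        nn.backward(-led, self.opt_eg.params)  # maximize
        self.opt_eg.step()

        record.update(
            loss_eg=led.item(), l1=l1.item(), lcel_e=lcel_e.item(),
            total=total_objective(led.item(), record["loss_d"]),
            entropy_dd=entropy_monitor(d_fake.class_logits),
        )
        for k, v in record.items():
            if not math.isfinite(v):
                raise FloatingPointError(f"non-finite loss {k}={v} at step {self.step}")
        self.step += 1
        return record

    def reconstruction_l1(self, images: np.ndarray) -> float:
        """Mean L1 between a batch and its eval-mode reconstruction."""
        self._set_eval()
        x = Tensor(images)
        logits, z = self.encoder(x)
        codes = np.argmax(logits.data, axis=1)
        onehot = np.zeros((codes.size, N_CLASSES))
        onehot[np.arange(codes.size), codes] = 1.0
        x_gen = self.generator(z, Tensor(onehot))
        return float(np.mean(np.abs(x.data - x_gen.data)))

    def sample_synthetic(
        self, class_counts, seed: int, out_dir=None
    ) -> tuple[list[LabeledImage], list[dict]]:
        """Generate exactly the requested per-class counts, deterministically."""
        import os

        from PIL import Image as PILImage

        from .labels import label_by_name

        self._set_eval()
        rng = np.random.default_rng(seed)
        images: list[LabeledImage] = []
        rows: list[dict] = []
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
        for lab_key in sorted(class_counts, key=lambda k: k.code if isinstance(k, ClassLabel) else label_by_name(k).code):
            lab = lab_key if isinstance(lab_key, ClassLabel) else label_by_name(lab_key)
            count = int(class_counts[lab_key])
            if count < 0:
                raise ValueError("generation counts must be non-negative")
            done = 0
            while done < count:
                b = min(64, count - done)
                z = rng.standard_normal((b, self.cfg.latent_dim))
                onehot = np.zeros((b, N_CLASSES))
                onehot[:, lab.code] = 1.0
                out = self.generator(Tensor(z), Tensor(onehot)).data
                for j in range(b):
                    pix = self.to_uint8(out[j])
                    img = LabeledImage(pix, label=lab, source="generated",
                                       id=f"gen-{lab.code}-{done + j:05d}")
                    path = ""
                    if out_dir is not None:
                        path = os.path.join(os.fspath(out_dir), f"{img.id}.png")
                        PILImage.fromarray(pix).save(path)
                    images.append(img)
                    rows.append({"id": img.id, "path": path, "class": lab.name,
                                 "source": "generated", "split": "train"})
                done += b
        return images, rows

    # -- checkpointing ---------------------------------------------------
    def save(self, path) -> None:
        arrays = (
            self.encoder.state_arrays()
            + self.generator.state_arrays()
            + self.discriminator.state_arrays()
        )
        np.savez_compressed(
            path, version=CHECKPOINT_VERSION, step=self.step,
            image_size=self.cfg.image_size, latent_dim=self.cfg.latent_dim,
            **{f"a{i}": a for i, a in enumerate(arrays)},
        )

    def load(self, path) -> None:
        with np.load(path) as data:
            if int(data["version"]) != CHECKPOINT_VERSION:
                raise ValueError("unsupported checkpoint version")
            arrays = [data[f"a{i}"] for i in range(len([k for k in data.files if k.startswith("a")]))]
            self.step = int(data["step"])
        n_e = len(self.encoder.state_arrays())
        n_g = len(self.generator.state_arrays())
        self.encoder.load_state_arrays(arrays[:n_e])
        self.generator.load_state_arrays(arrays[n_e : n_e + n_g])
        self.discriminator.load_state_arrays(arrays[n_e + n_g :])


def train_cvgan(
    state: CVGANState,
    images: list[LabeledImage],
    n_steps: int,
    probe_every: int = 0,
) -> list[dict[str, float]]:
    """Mini-batch training loop over a list of labelled images.

    Returns one loss record per step; when ``probe_every`` is set, records
    additionally carry an eval-mode reconstruction L1 probe.
    """
    cfg = state.cfg
    data = np.stack([state.to_model_range(im.pixels) for im in images])
    codes = np.array([im.label.code for im in images], dtype=np.int64)
    order_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2,)))
    history = []
    for step in range(n_steps):
        idx = order_rng.choice(len(images), size=min(cfg.batch_size, len(images)), replace=False)
        rec = state.train_step(data[idx], codes[idx])
        if probe_every and (step + 1) % probe_every == 0:
            rec["probe_l1"] = state.reconstruction_l1(data[idx])
        history.append(rec)
    return history
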
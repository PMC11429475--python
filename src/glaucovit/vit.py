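"""Dual-branch vision-transformer classifier with feature alignment.

A single shared transformer backbone maps an image to a length-5 score
vector: convolutional patch embedding with a learned positional code, a
stack of self-attention encoder layers, a decoder whose learned query
embeddings cross-attend to the encoder memory, mean pooling over the query
outputs, and a linear presence head.  During training the backbone is
applied to BOTH the photograph and its binary contour map, and the two
pre-softmax score vectors are summed (feature alignment):

    y_hat = ViT(X_contour) + ViT(X_image)

The loss is a class-weighted cross-entropy with inverse-frequency weights
``w_j = N / (C * n_j)``, so the scarce glaucoma grades are not drowned out
by the dominant classes.  At inference only the image branch is used — the
contour pipeline is never invoked — which makes the deployed model a plain
single-input classifier.

Because both branches share one parameter set, the image-only path is
exactly the trained backbone, not a separately-fitted twin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .labels import N_CLASSES, ClassLabel, label_by_code
from .nn import Tensor

PROB_EPS = 1e-12  # log(0) guard in the weighted cross-entropy


@dataclass(frozen=True)
class BackboneConfig:
    image_size: int = 512
    patch_size: int = 32  # conv-stem patch embedding stride
    hidden: int = 256
    n_encoder_layers: int = 6
    n_decoder_layers: int = 6
    n_heads: int = 8
    n_queries: int = 16
    mlp_ratio: int = 2
    dropout: float = 0.1
    n_classes: int = N_CLASSES
    lr: float = 1e-5
    weight_decay: float = 1e-6

    def __post_init__(self) -> None:
        if self.hidden % self.n_heads:
            raise ValueError("hidden size must be divisible by n_heads")
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def n_tokens(self) -> int:
        return (self.image_size // self.patch_size) ** 2


def desk_config(image_size: int = 64, lr: float = 3e-4) -> BackboneConfig:
    """CPU-sized configuration: 8x8 patch tokens, 2+2 layers, 2 heads."""
    return BackboneConfig(
        image_size=image_size, patch_size=image_size // 8, hidden=64,
        n_encoder_layers=2, n_decoder_layers=2, n_heads=2, n_queries=8,
        dropout=0.1, lr=lr,
    )


@dataclass
class Prediction:
    scores: np.ndarray  # (5,) probabilities summing to 1
    label: ClassLabel  # argmax; ties broken by smallest class code


class _EncoderLayer(nn.Module):
    def __init__(self, cfg: BackboneConfig, rng, drop_rng):
        self.ln1 = nn.LayerNorm(cfg.hidden)
        self.attn = nn.MultiHeadAttention(cfg.hidden, cfg.n_heads, rng)
        self.ln2 = nn.LayerNorm(cfg.hidden)
        self.fc1 = nn.Linear(cfg.hidden, cfg.mlp_ratio * cfg.hidden, rng)
        self.fc2 = nn.Linear(cfg.mlp_ratio * cfg.hidden, cfg.hidden, rng)
        self.drop = nn.Dropout(cfg.dropout, drop_rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.ln1(x)
        x = x + self.drop(self.attn(h, h, h))
        return x + self.drop(self.fc2(nn.relu(self.fc1(self.ln2(x)))))


class _DecoderLayer(nn.Module):
    def __init__(self, cfg: BackboneConfig, rng, drop_rng):
        self.ln1 = nn.LayerNorm(cfg.hidden)
        self.self_attn = nn.MultiHeadAttention(cfg.hidden, cfg.n_heads, rng)
        self.ln2 = nn.LayerNorm(cfg.hidden)
        self.cross_attn = nn.MultiHeadAttention(cfg.hidden, cfg.n_heads, rng)
        self.ln3 = nn.LayerNorm(cfg.hidden)
        self.fc1 = nn.Linear(cfg.hidden, cfg.mlp_ratio * cfg.hidden, rng)
        self.fc2 = nn.Linear(cfg.mlp_ratio * cfg.hidden, cfg.hidden, rng)
        self.drop = nn.Dropout(cfg.dropout, drop_rng)

    def __call__(self, q: Tensor, memory: Tensor) -> Tensor:
        h = self.ln1(q)
        q = q + self.drop(self.self_attn(h, h, h))
        q = q + self.drop(self.cross_attn(self.ln2(q), memory, memory))
        return q + self.drop(self.fc2(nn.relu(self.fc1(self.ln3(q)))))


class Backbone(nn.Module):
    """Patch-embedding encoder-decoder transformer with a linear head."""

    def __init__(self, cfg: BackboneConfig, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
        self.drop_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
        self.cfg = cfg
        self.stem = nn.Conv2d(3, cfg.hidden, cfg.patch_size, rng, stride=cfg.patch_size, padding=0)
        # small init keeps early attention near-uniform on flat inputs;
        # the embeddings grow as training differentiates positions
        self.pos = Tensor(
            rng.normal(0.0, 0.005, size=(1, cfg.n_tokens, cfg.hidden)), requires_grad=True
        )
        self.queries = Tensor(
            rng.normal(0.0, 0.005, size=(1, cfg.n_queries, cfg.hidden)), requires_grad=True
        )
        self.enc_layers = [_EncoderLayer(cfg, rng, self.drop_rng) for _ in range(cfg.n_encoder_layers)]
        self.dec_layers = [_DecoderLayer(cfg, rng, self.drop_rng) for _ in range(cfg.n_decoder_layers)]
        self.final_ln = nn.LayerNorm(cfg.hidden)
        self.head = nn.Linear(cfg.hidden, cfg.n_classes, rng)

    def features(self, x: Tensor) -> Tensor:
        """Pooled decoder output, (B, hidden)."""
        b = x.shape[0]
        if x.shape[2] != self.cfg.image_size or x.shape[3] != self.cfg.image_size:
            raise ValueError("input resolution does not match the backbone")
        tok = self.stem(x)  # (B, hidden, g, g)
        tok = nn.transpose(nn.reshape(tok, (b, self.cfg.hidden, -1)), (0, 2, 1))
        h = tok + self.pos
        for layer in self.enc_layers:
            h = layer(h)
        q = nn.broadcast_to(self.queries, (b,) + self.queries.shape[1:])
        for layer in self.dec_layers:
            q = layer(q, h)
        return nn.tmean(self.final_ln(q), axis=1)

    def __call__(self, x: Tensor) -> Tensor:
        return self.head(self.features(x))


def backbone_forward(backbone: Backbone, images: np.ndarray) -> np.ndarray:
    """Eval-mode score vectors for a uint8 batch (N, H, W, 3) -> (N, 5)."""
    backbone.set_training(False)
    return backbone(Tensor(to_model_range(images))).data


def to_model_range(images: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W, 3) -> float (N, 3, H, W) in [-1, 1]."""
    if images.ndim == 3:
        images = images[None]
    return images.astype(np.float64).transpose(0, 3, 1, 2) / 127.5 - 1.0


def align_features(f_img, f_contour):
    """Feature alignment: elementwise sum of the two pre-softmax score
    vectors produced by the shared backbone."""
    a_shape = f_img.shape if hasattr(f_img, "shape") else np.shape(f_img)
    b_shape = f_contour.shape if hasattr(f_contour, "shape") else np.shape(f_contour)
    if tuple(a_shape) != tuple(b_shape):
        raise ValueError("feature vectors must have equal length")
    return f_img + f_contour


def class_weights_from_counts(counts) -> np.ndarray:
    """Inverse-frequency class weights ``w_j = N / (C * n_j)`` with C = 5.

    ``counts`` maps class (label or name) to a positive count; classes absent
    from the map are treated as excluded and receive an inert weight of 1
    (they must not occur in the data).  A zero count raises: exclude the
    class from the map or smooth its count instead.
    """
    from .labels import label_by_name

    w = np.ones(N_CLASSES)
    n_total = 0
    entries: list[tuple[int, int]] = []
    for key, n in counts.items():
        lab = key if isinstance(key, ClassLabel) else label_by_name(key)
        if n <= 0:
            raise ValueError(
                f"class {lab.name!r} has zero count: exclude it from the weight map "
                "or smooth its count"
            )
        entries.append((lab.code, int(n)))
        n_total += int(n)
    for code, n in entries:
        w[code] = n_total / (N_CLASSES * n)
    return w


def weighted_cross_entropy(scores_batch, labels, weights) -> "Tensor | float":
    """Class-weighted categorical cross-entropy, batch-mean form:

        L = -(1/N) sum_i w_{y_i} log p_{i, y_i}

    ``scores_batch`` rows are probability vectors.  A true-class probability
    of zero is clamped at ``PROB_EPS`` with a warning.  With unit weights
    this equals the standard cross-entropy.
    """
    codes = np.asarray(
        [l.code if isinstance(l, ClassLabel) else int(l) for l in np.atleast_1d(labels)],
        dtype=np.int64,
    )
    if codes.min() < 0 or codes.max() >= N_CLASSES:
        raise ValueError("invalid class label")
    w = np.asarray(weights, dtype=np.float64)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("class weights must be positive and finite")
    wy = w[codes]
    is_tensor = isinstance(scores_batch, Tensor)
    probs_data = scores_batch.data if is_tensor else np.asarray(scores_batch, dtype=np.float64)
    probs_data = np.atleast_2d(probs_data)
    if np.any(probs_data[np.arange(codes.size), codes] < PROB_EPS):
        warnings.warn("true-class probability below epsilon; clamping log argument")
    if is_tensor:
        p = scores_batch if scores_batch.ndim == 2 else nn.reshape(scores_batch, (1, -1))
        picked = nn.take_patches(nn.reshape(p, (1, 1) + p.shape), np.arange(codes.size), codes)
        picked = nn.reshape(picked, (codes.size,))
        return -nn.tmean(nn.mul(Tensor(wy), nn.log(nn.clamp_min(picked, PROB_EPS))))
    picked = np.clip(probs_data[np.arange(codes.size), codes], PROB_EPS, None)
    return float(-np.mean(wy * np.log(picked)))


@dataclass
class ClassifierState:
    backbone: Backbone
    config: BackboneConfig
    class_weights: np.ndarray
    trained: bool = False


def predict(state: ClassifierState, image: np.ndarray) -> Prediction:
    """Image-only inference: softmax of the backbone scores.

    The contour pipeline is neither computed nor consumed here; ties in the
    argmax resolve to the smallest class code.
    """
    if not state.trained:
        warnings.warn("predicting with an untrained classifier")
    scores = backbone_forward(state.backbone, image[None] if image.ndim == 3 else image)
    z = scores - scores.max(axis=-1, keepdims=True)
    probs = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)
    p = probs[0]
    return Prediction(scores=p, label=label_by_code(int(np.argmax(p))))


class ClassifierTrainer:
    """Resumable dual-branch training loop.

    Every step computes the aligned scores ``backbone(image) +
    backbone(contour)`` with one shared backbone, takes their softmax, and
    minimizes the class-weighted cross-entropy whose weights come from the
    training-label distribution.  ``save``/``resume`` serialize the model,
    the optimizer moments and the data-order/dropout generator states, so a
    resumed run reproduces the loss trace of an uninterrupted one.
    """

    def __init__(
        self,
        images: np.ndarray,
        contours: np.ndarray | None,
        labels: np.ndarray,
        config: BackboneConfig,
        seed: int,
        batch_size: int = 32,
        val_data: tuple[np.ndarray, np.ndarray] | None = None,
    ):
        if contours is not None and len(images) != len(contours):
            raise ValueError("every training record needs both an image and its contour map")
        if len(images) != len(labels):
            raise ValueError("images and labels must have equal length")
        self.codes = np.asarray(labels, dtype=np.int64)
        counts = {label_by_code(c): int(n)
                  for c, n in zip(*np.unique(self.codes, return_counts=True))}
        self.weights = class_weights_from_counts(counts)
        self.config = config
        self.batch_size = batch_size
        self.val_data = val_data
        self.backbone = Backbone(config, seed=seed)
        self.opt = nn.Adam(self.backbone.parameters(), lr=config.lr, betas=(0.9, 0.999),
                           weight_decay=config.weight_decay)
        self.order_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
        self.x_img = to_model_range(images)
        # contours=None trains the image branch alone (the ablation mode)
        self.x_con = to_model_range(contours) if contours is not None else None
        self.epoch = 0
        self.history: list[dict[str, float]] = []

    def run(self, n_epochs: int) -> list[dict[str, float]]:
        n = len(self.codes)
        for _ in range(n_epochs):
            self.backbone.set_training(True)
            perm = self.order_rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, self.batch_size):
                idx = perm[start : start + self.batch_size]
                img_scores = self.backbone(Tensor(self.x_img[idx]))
                if self.x_con is None:
                    aligned = img_scores
                else:
                    aligned = align_features(img_scores,
                                             self.backbone(Tensor(self.x_con[idx])))
                probs = nn.softmax(aligned, axis=-1)
                loss = weighted_cross_entropy(probs, self.codes[idx], self.weights)
                self.opt.zero_grad()
                nn.backward(loss, self.opt.params)
                self.opt.step()
                losses.append(loss.item())
                correct += int(np.sum(np.argmax(aligned.data, axis=1) == self.codes[idx]))
            rec = {"epoch": float(self.epoch), "train_loss": float(np.mean(losses)),
                   "train_acc": correct / n}
            if self.val_data is not None:
                vx, vy = self.val_data
                scores = _batched_scores(self.backbone, vx)
                rec["val_acc"] = float(np.mean(np.argmax(scores, axis=1) == np.asarray(vy)))
            self.history.append(rec)
            self.epoch += 1
        return self.history

    def state(self) -> ClassifierState:
        return ClassifierState(backbone=self.backbone, config=self.config,
                               class_weights=self.weights, trained=self.epoch > 0)

    def save(self, path) -> None:
        import json

        arrays = self.backbone.state_arrays() + self.opt.m + self.opt.v
        rng_state = json.dumps({
            "order": self.order_rng.bit_generator.state,
            "drop": self.backbone.drop_rng.bit_generator.state,
        })
        np.savez_compressed(
            path, version=CHECKPOINT_VERSION, epoch=self.epoch, t=self.opt.t,
            rng_state=rng_state, class_weights=self.weights,
            **{f"a{i}": a for i, a in enumerate(arrays)},
        )

    def resume(self, path) -> None:
        import json

        with np.load(path) as data:
            if int(data["version"]) != CHECKPOINT_VERSION:
                raise ValueError("unsupported training checkpoint version")
            arrays = [data[f"a{i}"]
                      for i in range(len([k for k in data.files if k.startswith("a")]))]
            n_model = len(self.backbone.state_arrays())
            n_p = len(self.opt.params)
            self.backbone.load_state_arrays(arrays[:n_model])
            self.opt.m = [a.astype(np.float64) for a in arrays[n_model : n_model + n_p]]
            self.opt.v = [a.astype(np.float64) for a in arrays[n_model + n_p :]]
            self.opt.t = int(data["t"])
            self.epoch = int(data["epoch"])
            rng_state = json.loads(str(data["rng_state"]))
        self.order_rng.bit_generator.state = rng_state["order"]
        self.backbone.drop_rng.bit_generator.state = rng_state["drop"]


def train_classifier(
    images: np.ndarray,
    contours: np.ndarray,
    labels: np.ndarray,
    config: BackboneConfig,
    seed: int,
    epochs: int = 10,
    batch_size: int = 32,
    val_data: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[ClassifierState, list[dict[str, float]]]:
    """Fit the dual-branch classifier on (image, contour, label) triples.

    Validation accuracy (image branch only, matching inference) is recorded
    per epoch when ``val_data = (val_images, val_labels)`` is given.  Fully
    deterministic under ``seed``.
    """
    trainer = ClassifierTrainer(images, contours, labels, config, seed,
                                batch_size=batch_size, val_data=val_data)
    history = trainer.run(epochs)
    return trainer.state(), history


def _batched_scores(backbone: Backbone, images: np.ndarray, batch: int = 64) -> np.ndarray:
    out = []
    for start in range(0, len(images), batch):
        out.append(backbone_forward(backbone, images[start : start + batch]))
    return np.concatenate(out, axis=0)


def evaluate_accuracy(state: ClassifierState, images: np.ndarray, labels: np.ndarray) -> float:
    scores = _batched_scores(state.backbone, images)
    return float(np.mean(np.argmax(scores, axis=1) == np.asarray(labels)))


def export_features(state: ClassifierState, images: np.ndarray) -> np.ndarray:
    """Pooled backbone features per image, for external embedding (e.g. t-SNE)."""
    state.backbone.set_training(False)
    out = []
    for start in range(0, len(images), 64):
        x = Tensor(to_model_range(images[start : start + 64]))
        out.append(state.backbone.features(x).data)
    return np.concatenate(out, axis=0)


def export_attention_maps(
    state: ClassifierState, image: np.ndarray, layer: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Decoder cross-attention maps per head.

    Returns ``(pre, up)`` where ``pre`` has shape (n_layers, n_heads,
    n_tokens) with each head's map summing to 1 over spatial positions
    (mean over queries of the attention rows), and ``up`` is the same maps
    nearest-neighbour upsampled to image resolution.
    """
    backbone = state.backbone
    backbone_forward(backbone, image[None] if image.ndim == 3 else image)
    layers = backbone.dec_layers if layer is None else [backbone.dec_layers[layer]]
    cfg = state.config
    g = cfg.image_size // cfg.patch_size
    pre = np.stack([lay.cross_attn.last_attention[0].mean(axis=1) for lay in layers])
    up = np.kron(pre.reshape(len(layers), cfg.n_heads, g, g),
                 np.ones((cfg.patch_size, cfg.patch_size)))
    return pre, up


# -- checkpointing -------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_classifier(state: ClassifierState, path) -> None:
    arrays = state.backbone.state_arrays()
    np.savez_compressed(
        path, version=CHECKPOINT_VERSION, class_weights=state.class_weights,
        image_size=state.config.image_size, patch_size=state.config.patch_size,
        hidden=state.config.hidden, n_encoder_layers=state.config.n_encoder_layers,
        n_decoder_layers=state.config.n_decoder_layers, n_heads=state.config.n_heads,
        n_queries=state.config.n_queries, dropout=state.config.dropout,
        lr=state.config.lr, weight_decay=state.config.weight_decay,
        mlp_ratio=state.config.mlp_ratio,
        **{f"a{i}": a for i, a in enumerate(arrays)},
    )


def load_classifier(path) -> ClassifierState:
    with np.load(path) as data:
        if "version" not in data.files or int(data["version"]) != CHECKPOINT_VERSION:
            raise ValueError("corrupt or unsupported classifier checkpoint")
        cfg = BackboneConfig(
            image_size=int(data["image_size"]), patch_size=int(data["patch_size"]),
            hidden=int(data["hidden"]), n_encoder_layers=int(data["n_encoder_layers"]),
            n_decoder_layers=int(data["n_decoder_layers"]), n_heads=int(data["n_heads"]),
            n_queries=int(data["n_queries"]), mlp_ratio=int(data["mlp_ratio"]),
            dropout=float(data["dropout"]), lr=float(data["lr"]),
            weight_decay=float(data["weight_decay"]),
        )
        backbone = Backbone(cfg, seed=0)
        arrays = [data[f"a{i}"] for i in range(len([k for k in data.files if k.startswith("a")]))]
        backbone.load_state_arrays(arrays)
        weights = data["class_weights"]
    return ClassifierState(backbone=backbone, config=cfg, class_weights=weights, trained=True)
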
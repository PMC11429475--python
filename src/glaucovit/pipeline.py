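"""Three-phase orchestration: data generation, training, inference.

Phase 1 enlarges the training split with classical augmentation (per-class
budgets) and conditional-GAN samples, and extracts one contour map per
training record.  Phase 2 trains the dual-branch classifier on the
(image, contour) pairs.  Phase 3 predicts from original images only — the
contour pipeline is never invoked at inference.

Manifests are plain tables with columns ``id, path, class, source, split``;
records are only ever added (generation) or annotated (splitting), never
silently removed.  Augmented and generated records always carry
``split="train"``.  All stochastic steps derive their seeds from the master
seed, and every phase logs its per-class ledger totals.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .augment import AugmentationPolicy, run_augmentation
from .contour import ContourParams, contour_to_image, extract_contour
from .labels import ALL_LABELS, GENERATION_LEDGER, SMDG_SOURCE_COUNTS, label_by_name
from .metrics import MetricReport, confusion_matrix, multiclass_report
from .phantom import LabeledImage
from .vit import (
    BackboneConfig,
    ClassifierState,
    Prediction,
    desk_config,
    export_features,
    predict,
    train_classifier,
)

logger = logging.getLogger("glaucovit")

MANIFEST_COLUMNS = ["id", "path", "class", "source", "split"]


@dataclass
class PipelineConfig:
    """One structured configuration for all three phases."""

    image_size: int = 64
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    augment_budgets: dict = field(
        default_factory=lambda: {c: v["augmented"] for c, v in GENERATION_LEDGER.items()}
    )
    cvgan_budgets: dict = field(
        default_factory=lambda: {c: v["cvgan"] for c, v in GENERATION_LEDGER.items()}
    )
    contour_kernel: int = 5
    contour_low: float = 0.10
    contour_high: float = 0.30
    epochs: int = 10
    batch_size: int = 50
    master_seed: int = 0
    out_root: str = "runs"

    def __post_init__(self) -> None:
        f = self.split_fractions
        if min(f) <= 0 or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")

    def contour_params(self) -> ContourParams:
        return ContourParams(
            gaussian_kernel=self.contour_kernel,
            low_threshold=self.contour_low,
            high_threshold=self.contour_high,
        )

    def backbone(self) -> BackboneConfig:
        return desk_config(image_size=self.image_size)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def build_manifest(
    source_counts: Mapping[str, Mapping[str, int]] | None = None,
    image_root: str = "",
) -> pd.DataFrame:
    """One record per image from a {dataset: {class: count}} table.

    Defaults to the SMDG-19 source overview (11,665 records).  Paths are
    synthesized under ``image_root`` and not required to exist; validation
    against disk is a separate explicit step.
    """
    source_counts = SMDG_SOURCE_COUNTS if source_counts is None else source_counts
    rows = []
    for ds, counts in source_counts.items():
        for cls, n in counts.items():
            lab = label_by_name(cls)
            if n < 0:
                raise ValueError("counts must be non-negative")
            for i in range(int(n)):
                rid = f"{ds}-{lab.code}-{i:05d}"
                rows.append({
                    "id": rid,
                    "path": f"{image_root}/{rid}.png" if image_root else "",
                    "class": cls, "source": "original", "split": "",
                })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    _log_ledger("build_manifest", manifest)
    return manifest


def ledger_train_manifest() -> pd.DataFrame:
    """Original-train records per the published generation ledger.

    Its suspect count (27) differs from the source-table suspect sum (25);
    the discrepancy is logged, not resolved.
    """
    rows = []
    for cls, v in GENERATION_LEDGER.items():
        lab = label_by_name(cls)
        for i in range(v["original_train"]):
            rows.append({"id": f"train-{lab.code}-{i:05d}", "path": "",
                         "class": cls, "source": "original", "split": "train"})
    from .labels import smdg_class_totals

    src = smdg_class_totals()
    for cls, v in GENERATION_LEDGER.items():
        if v["original_train"] > src[cls]:
            logger.warning(
                "generation ledger lists %d original %s records but the source "
                "table sums to %d; ledgers kept as published",
                v["original_train"], cls, src[cls],
            )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def split_dataset(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified train/val/test assignment of the ORIGINAL records.

    Per class, ``round(f_train * n)`` records go to train and
    ``round(f_val * n)`` to val, the remainder to test, under a seeded
    permutation.  Augmented/generated records are train-only by construction
    and keep their split.  Classes with fewer than 3 records go entirely to
    train with a warning.
    """
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    for cls in out.loc[out["source"] == "original", "class"].unique():
        idx = out.index[(out["source"] == "original") & (out["class"] == cls)].to_numpy()
        n = len(idx)
        if n < 3:
            logger.warning("class %s has only %d records; assigning all to train", cls, n)
            out.loc[idx, "split"] = "train"
            continue
        perm = idx[rng.permutation(n)]
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        out.loc[perm[:n_train], "split"] = "train"
        out.loc[perm[n_train : n_train + n_val], "split"] = "val"
        out.loc[perm[n_train + n_val :], "split"] = "test"
    _log_ledger("split_dataset", out)
    return out


def run_generation_phase(
    manifest: pd.DataFrame,
    config: PipelineConfig,
    images: dict[str, LabeledImage] | None = None,
    cvgan_state=None,
) -> tuple[pd.DataFrame, dict[str, LabeledImage], dict[str, np.ndarray]]:
    """Enlarge the training split per the augmentation and GAN budgets.

    With ``images`` (and, for generation, ``cvgan_state``) supplied, real
    pixels are produced and a contour map is extracted for every training
    record; without them the phase runs in dry-run ledger mode and only the
    manifest grows.  Per-class budgets are counts of new records; the
    combined augmented+generated totals form the generation-phase ledger.
    """
    for cls, target in config.augment_budgets.items():
        pool = manifest[(manifest["source"] == "original") & (manifest["class"] == cls)]
        if target > 0 and pool.empty:
            raise ValueError(f"augmentation budget for empty class {cls!r}")

    policy = AugmentationPolicy(
        target_counts=dict(config.augment_budgets),
        seed=int(np.random.SeedSequence(config.master_seed, spawn_key=(10,)).generate_state(1)[0] % 2**31),
    )
    out, aug_images = run_augmentation(manifest, policy, images=images)

    gen_rows: list[dict] = []
    gen_images: list[LabeledImage] = []
    if cvgan_state is not None and images is not None:
        seed = int(np.random.SeedSequence(config.master_seed, spawn_key=(11,)).generate_state(1)[0] % 2**31)
        gen_images, gen_rows = cvgan_state.sample_synthetic(config.cvgan_budgets, seed=seed)
    else:
        for cls, count in config.cvgan_budgets.items():
            lab = label_by_name(cls)
            for i in range(int(count)):
                gen_rows.append({"id": f"gen-{lab.code}-{i:05d}", "path": "", "class": cls,
                                 "source": "generated", "split": "train"})
    if gen_rows:
        out = pd.concat([out, pd.DataFrame(gen_rows, columns=MANIFEST_COLUMNS)], ignore_index=True)

    all_images: dict[str, LabeledImage] = dict(images or {})
    for im in aug_images + gen_images:
        all_images[im.id] = im

    contours: dict[str, np.ndarray] = {}
    if images is not None:
        params = config.contour_params()
        train_ids = out.loc[out["split"] == "train", "id"]
        for rid in train_ids:
            contours[rid] = contour_to_image(extract_contour(all_images[rid], params))
        assert len(contours) == int((out["split"] == "train").sum())

    combined = out[out["source"].isin(["augmented", "generated"])]
    logger.info(
        "generation phase: %d augmented + %d generated = %d combined training records",
        int((out["source"] == "augmented").sum()),
        int((out["source"] == "generated").sum()),
        len(combined),
    )
    _log_ledger("generation_phase", out)
    if not out["id"].is_unique:
        raise ValueError("manifest ids must stay unique across phases")
    return out, all_images, contours


def combined_training_counts(manifest: pd.DataFrame) -> dict[str, int]:
    """Per-class augmented+generated record counts (the generation ledger)."""
    m = manifest[manifest["source"].isin(["augmented", "generated"])]
    return {cls: int((m["class"] == cls).sum()) for cls in sorted(m["class"].unique())}


def run_training_phase(
    manifest: pd.DataFrame,
    images: dict[str, LabeledImage],
    contours: dict[str, np.ndarray],
    config: PipelineConfig,
) -> tuple[ClassifierState, list[dict]]:
    """Train the dual-branch classifier on all training records."""
    train = manifest[manifest["split"] == "train"]
    missing = [rid for rid in train["id"] if rid not in contours]
    if missing:
        raise ValueError(f"{len(missing)} training records lack contour maps (e.g. {missing[0]!r})")
    x = np.stack([images[rid].pixels for rid in train["id"]])
    c = np.stack([contours[rid] for rid in train["id"]])
    y = np.array([label_by_name(cl).code for cl in train["class"]])
    val = manifest[manifest["split"] == "val"]
    val_data = None
    if len(val):
        vx = np.stack([images[rid].pixels for rid in val["id"]])
        vy = np.array([label_by_name(cl).code for cl in val["class"]])
        val_data = (vx, vy)
    state, history = train_classifier(
        x, c, y, config.backbone(), seed=config.master_seed,
        epochs=config.epochs, batch_size=config.batch_size, val_data=val_data,
    )
    return state, history


def run_inference_phase(
    state: ClassifierState,
    images: list[LabeledImage] | dict[str, LabeledImage],
    with_truth: bool = True,
) -> tuple[pd.DataFrame, MetricReport | None]:
    """Image-only predictions; adds the full metric report when labels exist."""
    items = list(images.values()) if isinstance(images, dict) else list(images)
    rows = []
    preds: list[Prediction] = []
    for im in items:
        p = predict(state, im.pixels)
        preds.append(p)
        rows.append({"id": im.id, "predicted": p.label.name,
                     **{f"p_{lab.name}": p.scores[lab.code] for lab in ALL_LABELS}})
    df = pd.DataFrame(rows)
    report = None
    if with_truth:
        cm = confusion_matrix(
            [im.label.code for im in items], [p.label.code for p in preds]
        )
        report = multiclass_report(cm)
    return df, report


def export_features_table(state: ClassifierState, images: list[LabeledImage]) -> pd.DataFrame:
    feats = export_features(state, np.stack([im.pixels for im in images]))
    df = pd.DataFrame(feats, columns=[f"f{i}" for i in range(feats.shape[1])])
    df.insert(0, "id", [im.id for im in images])
    df.insert(1, "class", [im.label.name for im in images])
    return df


def _log_ledger(phase: str, manifest: pd.DataFrame) -> None:
    counts = manifest.groupby("class").size().to_dict()
    logger.info("%s ledger: %s (total %d)", phase, counts, len(manifest))
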
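"""Synthetic fundus phantoms with class-conditional disc/cup geometry.

A phantom emulates the features of a colour fundus photograph that the rest
of the toolchain depends on: a bright elliptical optic disc containing a
brighter optic cup (the cup-to-disc ratio, CDR, grows with glaucoma
severity), darker curvilinear vessels, a smooth illumination gradient and
additive sensor noise.  Identical spec + seed always yields a bit-identical
image, so every downstream module is testable without real data.

Photorealism is an explicit non-goal; the phantom carries exactly the
structure that the contour operators and the circular-Hough disc locator are
designed to detect.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image

from .labels import ALL_LABELS, ClassLabel

# Noiseless construction levels (8-bit intensity).
BACKGROUND_LEVEL = 40.0
DISC_LEVEL = 150.0
CUP_LEVEL = 220.0
VESSEL_LEVEL = 25.0

# Default cup-to-disc ratio per class: clinically plausible ordering with
# cupping increasing from normal to glaucoma.  Fixture constants, overridable
# through configuration.
DEFAULT_CLASS_CDR: dict[str, float] = {
    "normal": 0.30,
    "suspect": 0.45,
    "referable": 0.55,
    "POAG/NTG": 0.60,
    "glaucoma": 0.70,
}


class PhantomSpecError(ValueError):
    """Raised when a phantom specification violates its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and nuisance parameters of one phantom image.

    ``disc_center`` is (row, col) in pixels, 0-based.  ``noise_sigma`` is in
    8-bit intensity units; ``illumination_slope`` is intensity units per
    pixel along the column axis.
    """

    image_size: int = 64
    disc_center: tuple[float, float] = (32.0, 32.0)
    disc_radius: float = 14.0
    cup_to_disc_ratio: float = 0.5
    n_vessels: int = 3
    noise_sigma: float = 4.0
    illumination_slope: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise PhantomSpecError("image_size must be positive")
        if not 0.0 < self.cup_to_disc_ratio < 1.0:
            raise PhantomSpecError("cup_to_disc_ratio must lie in (0, 1)")
        if self.n_vessels < 0 or self.noise_sigma < 0:
            raise PhantomSpecError("n_vessels and noise_sigma must be non-negative")
        if self.disc_radius <= 0:
            raise PhantomSpecError("disc_radius must be positive")
        r, c = self.disc_center
        rad = self.disc_radius
        n = self.image_size
        if r - rad < 0 or c - rad < 0 or r + rad > n - 1 or c + rad > n - 1:
            raise PhantomSpecError("optic disc must lie fully inside the image frame")
        if self.seed < 0:
            raise PhantomSpecError("seed must be non-negative")

    @property
    def cup_radius(self) -> float:
        return self.cup_to_disc_ratio * self.disc_radius


@dataclass
class LabeledImage:
    """An 8-bit RGB image with its grade label and provenance tag."""

    pixels: np.ndarray  # (H, W, 3) uint8
    label: ClassLabel
    source: str = "original"  # original | augmented | generated
    id: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 grid")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit")
        if self.source not in ("original", "augmented", "generated"):
            raise ValueError(f"unknown provenance tag {self.source!r}")


def class_default_cdr(label: ClassLabel) -> float:
    """Default cup-to-disc ratio for a grade; strictly increasing with severity."""
    try:
        return DEFAULT_CLASS_CDR[label.name]
    except (KeyError, AttributeError):
        raise ValueError(f"unknown label {label!r}") from None


def _disk_mask(n: int, center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0:n, 0:n]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def render_phantom(spec: PhantomSpec, label: ClassLabel) -> LabeledImage:
    """Render one phantom deterministically from its spec and seed.

    The disc is strictly brighter (in mean) than the background and the cup
    strictly brighter than the disc annulus, mirroring the relative
    brightness of the optic cup against the surrounding disc on real fundus
    photographs.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    img = np.full((n, n), BACKGROUND_LEVEL, dtype=np.float64)

    # Vessels: darker random-walk polylines radiating from near the disc.
    for _ in range(spec.n_vessels):
        r = float(rng.uniform(0, n - 1))
        c = float(rng.uniform(0, n - 1))
        angle = float(rng.uniform(0, 2 * np.pi))
        for _ in range(int(2.5 * n)):
            ri, ci = int(round(r)), int(round(c))
            if 0 <= ri < n and 0 <= ci < n:
                img[ri, ci] = VESSEL_LEVEL
            angle += float(rng.normal(0.0, 0.25))
            r += np.sin(angle)
            c += np.cos(angle)

    disc = _disk_mask(n, spec.disc_center, spec.disc_radius)
    cup = _disk_mask(n, spec.disc_center, spec.cup_radius)
    img[disc] = DISC_LEVEL
    img[cup] = CUP_LEVEL

    cols = np.arange(n, dtype=np.float64)
    img = img + spec.illumination_slope * (cols - (n - 1) / 2.0)[None, :]

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=(n, n))

    img8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return LabeledImage(np.repeat(img8[:, :, None], 3, axis=2), label=label, source="original")


def per_image_seed(master_seed: int, class_code: int, index: int) -> int:
    """Deterministic, well-mixed per-image seed below 2**31."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(class_code, index))
    return int(ss.generate_state(1)[0] % (2**31))


def _jittered_spec(template: PhantomSpec, label: ClassLabel, seed: int) -> PhantomSpec:
    """Per-image geometry jitter so a dataset is not one repeated frame."""
    rng = np.random.default_rng(seed)
    n = template.image_size
    rad = template.disc_radius * float(rng.uniform(0.85, 1.15))
    rad = min(rad, (n - 1) / 2.0 - 1.0)
    lo, hi = rad, n - 1 - rad
    center = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
    cdr = float(np.clip(class_default_cdr(label) + rng.uniform(-0.04, 0.04), 0.05, 0.95))
    return replace(
        template, disc_center=center, disc_radius=rad, cup_to_disc_ratio=cdr, seed=seed
    )


def generate_dataset(
    class_counts: Mapping[ClassLabel, int] | Mapping[str, int],
    spec_template: PhantomSpec,
    seed: int,
    out_dir: str | os.PathLike[str] | None = None,
    jitter: bool = True,
) -> tuple[pd.DataFrame, list[LabeledImage]]:
    """Render a phantom dataset and its manifest.

    Returns the manifest (columns ``id, path, class, source, split``) and the
    rendered images.  When ``out_dir`` is given every image is written as a
    PNG and the manifest paths point at the files; otherwise paths are empty.
    Per-image seeds derive deterministically from ``seed`` so two master
    seeds give distinct datasets while one seed is fully reproducible.
    """
    norm_counts: dict[ClassLabel, int] = {}
    for key, cnt in class_counts.items():
        lab = key if isinstance(key, ClassLabel) else _lookup(key)
        if cnt < 0:
            raise ValueError(f"count for {lab.name!r} must be >= 0")
        norm_counts[lab] = int(cnt)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)

    rows = []
    images: list[LabeledImage] = []
    for lab in ALL_LABELS:
        for i in range(norm_counts.get(lab, 0)):
            img_seed = per_image_seed(seed, lab.code, i)
            spec = (
                _jittered_spec(spec_template, lab, img_seed)
                if jitter
                else replace(
                    spec_template,
                    cup_to_disc_ratio=class_default_cdr(lab),
                    seed=img_seed,
                )
            )
            image = render_phantom(spec, lab)
            image.id = f"phantom-{lab.code}-{i:05d}"
            path = ""
            if out_dir is not None:
                path = os.path.join(os.fspath(out_dir), f"{image.id}.png")
                Image.fromarray(image.pixels).save(path)
            rows.append(
                {"id": image.id, "path": path, "class": lab.name, "source": "original", "split": ""}
            )
            images.append(image)
    return pd.DataFrame(rows, columns=["id", "path", "class", "source", "split"]), images


def _lookup(name: str) -> ClassLabel:
    from .labels import label_by_name

    return label_by_name(name)
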
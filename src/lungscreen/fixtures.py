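"""Seeded synthetic datasets with known ground truth.

Real chest-radiograph collections cannot ship with the package, so every
downstream stage is exercised on synthetic data instead:

* :func:`make_image_dataset` draws class-labeled grayscale-like RGB images
  whose texture differs by class — band-pass filtered Gaussian noise at a
  class-specific spatial frequency and contrast, plus a class-specific smooth
  sinusoidal shading component, composited over a shared elliptical
  "lung field" mask.  The classes are statistically separable (a raw-pixel
  nearest-neighbor already beats chance) without pretending to anatomical
  realism.
* :func:`make_feature_table` builds tabular fixtures for the selector and
  classifier stages: standard-normal noise columns plus a known set of
  informative columns whose class means are shifted by a chosen effect size.
  The planted indices are recorded so recovery can be scored exactly.

Both are bit-reproducible: same spec + same seed => identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .containers import FeatureMatrix, ImageSet
from .errors import ValidationError

DEFAULT_CLASSES = ("normal", "pneumonia", "covid19")

#: Per-class texture settings: band-pass sigmas (narrower = higher spatial
#: frequency), noise contrast, shading orientation (radians) and brightness.
DEFAULT_TEXTURE_PARAMS = {
    "normal": {"sigma_lo": 6.0, "sigma_hi": 12.0, "contrast": 0.25,
               "angle": 0.0, "brightness": 0.45},
    "pneumonia": {"sigma_lo": 2.5, "sigma_hi": 6.0, "contrast": 0.45,
                  "angle": 1.1, "brightness": 0.60},
    "covid19": {"sigma_lo": 1.0, "sigma_hi": 2.5, "contrast": 0.65,
                "angle": 2.2, "brightness": 0.75},
}


@dataclass
class FixtureSpec:
    """Recipe for a synthetic image dataset."""

    n_per_class: int
    classes: tuple[str, ...] = DEFAULT_CLASSES
    image_size: tuple[int, int, int] = (256, 256, 3)
    texture_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValidationError(f"n_per_class must be >= 1, got {self.n_per_class}")
        h, w, c = self.image_size
        if h < 4 or w < 4 or c != 3:
            raise ValidationError(f"image_size must be (h>=4, w>=4, 3), got {self.image_size}")

    def params_for(self, label: str, index: int) -> dict:
        if label in self.texture_params:
            return self.texture_params[label]
        if label in DEFAULT_TEXTURE_PARAMS:
            return DEFAULT_TEXTURE_PARAMS[label]
        # unseen class name: derive settings from its position
        base = list(DEFAULT_TEXTURE_PARAMS.values())
        return base[index % len(base)]


def _lung_mask(h: int, w: int) -> np.ndarray:
    """Soft elliptical mask shared by all classes (a stylized thorax)."""
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = ((yy - cy) / (0.42 * h)) ** 2 + ((xx - cx) / (0.36 * w)) ** 2
    return np.clip(1.25 - r, 0.0, 1.0)


def _class_image(h: int, w: int, p: dict, rng: np.random.Generator) -> np.ndarray:
    """One (h, w) float plane in [0, 1] with the class's texture statistics."""
    noise = rng.standard_normal((h, w))
    band = ndimage.gaussian_filter(noise, p["sigma_lo"]) - \
        ndimage.gaussian_filter(noise, p["sigma_hi"])
    sd = band.std()
    if sd > 0:
        band = band / sd
    yy, xx = np.mgrid[0:h, 0:w]
    t = (np.cos(p["angle"]) * xx + np.sin(p["angle"]) * yy) / max(h, w)
    shading = 0.5 + 0.5 * np.sin(2.0 * np.pi * 1.5 * t)
    mask = _lung_mask(h, w)
    # deterministic class components (brightness + oriented shading) outweigh
    # the per-image noise so raw-pixel distances already separate the classes
    plane = mask * (0.5 * p["brightness"] + 0.35 * shading +
                    0.2 * p["contrast"] * band) + 0.05
    return np.clip(plane, 0.0, 1.0)


def make_image_dataset(spec: FixtureSpec) -> ImageSet:
    """Generate ``n_per_class x |classes|`` labeled synthetic images.

    Returns an :class:`ImageSet` of uint8 arrays shaped ``image_size`` with
    values in [0, 255], grouped by class in ``spec.classes`` order.
    """
    h, w, _ = spec.image_size
    rng = np.random.default_rng(spec.seed)
    images: list[np.ndarray] = []
    labels: list[str] = []
    ids: list[str] = []
    for ci, label in enumerate(spec.classes):
        p = spec.params_for(label, ci)
        for i in range(spec.n_per_class):
            plane = _class_image(h, w, p, rng)
            img = np.repeat(plane[:, :, None], 3, axis=2)
            images.append(np.round(img * 255.0).astype(np.uint8))
            labels.append(label)
            ids.append(f"{label}_{i:04d}")
    return ImageSet(images=images, labels=labels, ids=ids)


def make_feature_table(
    n_per_class: int,
    d: int,
    n_informative: int,
    effect: float,
    seed: int,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
) -> FeatureMatrix:
    """Tabular fixture: noise columns plus planted class-informative columns.

    Every column is standard normal; in the ``n_informative`` planted columns
    class ``c`` additionally receives a mean shift of
    ``effect * (c - (C-1)/2) / max(1, (C-1)/2)`` so adjacent class means
    differ by about ``effect`` (in units of the noise standard deviation).
    Planted column positions are drawn without replacement and recorded in
    ``metadata['informative_indices']``.
    """
    if n_per_class < 1 or d < 1:
        raise ValidationError("n_per_class and d must be positive")
    if n_informative > d:
        raise ValidationError(f"n_informative ({n_informative}) > d ({d})")
    rng = np.random.default_rng(seed)
    n_classes = len(classes)
    n = n_per_class * n_classes
    X = rng.standard_normal((n, d))
    informative = np.sort(rng.choice(d, size=n_informative, replace=False))
    labels = np.repeat(list(classes), n_per_class)
    half_span = max(1.0, (n_classes - 1) / 2.0)
    for ci in range(n_classes):
        shift = effect * (ci - (n_classes - 1) / 2.0) / half_span
        rows = slice(ci * n_per_class, (ci + 1) * n_per_class)
        X[rows, informative] += shift
    return FeatureMatrix(
        values=X,
        labels=labels,
        block_map=[("synthetic", 0, d)],
        sample_ids=[f"{lab}_{i % n_per_class:04d}" for i, lab in enumerate(labels)],
        metadata={"informative_indices": informative.tolist(),
                  "effect": effect, "seed": seed},
    )
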
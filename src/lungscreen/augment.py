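"""Image preprocessing, stationary-wavelet augmentation, and dataset splits.

The augmentation scheme enlarges a training set nine-fold: each normalized
image is decomposed with a 3-level 2-D stationary (undecimated) wavelet
transform using the Daubechies db2 filter; the three per-level approximation
planes, rescaled back to [0, 1], become three derived images; and each of
those receives one random translation, one random rotation, and one random
shear, yielding 3 levels x 3 geometric operations = 9 augmented images per
source.  The originals are replaced, not appended, so a class of 2456
training images becomes exactly 22,104.

The undecimated transform keeps every coefficient plane at the input's
spatial size and, with periodic boundary handling, is equivariant under
circular shifts — the property that makes it attractive for augmenting
texture statistics without resampling artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pywt
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .containers import ImageSet
from .errors import ConfigurationError, DegenerateImageError, ValidationError
from .seeding import child_seed


@dataclass
class NormalizedImage:
    """A (h, w, 3) float image min-max rescaled to [0, 1], with provenance."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError(
                f"normalized image must be (h, w, 3), got {self.pixels.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class SwtStack:
    """Per-level stationary-wavelet coefficient planes of one image.

    Arrays are ``(h, w, 3, n)``: spatial size preserved (undecimated), three
    channels, ``n`` decomposition levels with index 0 = level 1 (finest).
    ``app`` holds the approximation (low-frequency) planes; ``ver``, ``hor``,
    ``dia`` the vertical/horizontal/diagonal detail planes.
    """

    app: np.ndarray
    ver: np.ndarray
    hor: np.ndarray
    dia: np.ndarray
    wavelet_name: str = "db2"
    source_id: str = ""
    pad: tuple[tuple[int, int], tuple[int, int]] = ((0, 0), (0, 0))
    original_shape: tuple[int, int] | None = None

    @property
    def levels(self) -> int:
        return self.app.shape[3]


@dataclass
class AugmentationParams:
    """Ranges for the three random geometric operations (low, high)."""

    translation_range: tuple[float, float] = (-10.0, 10.0)
    rotation_range: tuple[float, float] = (-90.0, 90.0)
    shear_range: tuple[float, float] = (-30.0, 30.0)
    fill_mode: str = "zeros"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("translation_range", "rotation_range", "shear_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} must satisfy low <= high, got ({lo}, {hi})")
        if self.fill_mode != "zeros":
            raise ConfigurationError(f"unsupported fill_mode {self.fill_mode!r}")


@dataclass
class SplitSpec:
    """Stratified train/validation/test ratios; default 60/25/15."""

    ratios: tuple[float, float, float] = (0.60, 0.25, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.ratios):
            raise ValidationError("split ratios must be non-negative")
        if not math.isclose(sum(self.ratios), 1.0, abs_tol=1e-9):
            raise ValidationError(f"split ratios must sum to 1, got {self.ratios}")


# ---------------------------------------------------------------------------
# normalization / resizing


def normalize_minmax(image: np.ndarray, source_id: str = "") -> NormalizedImage:
    """Rescale an image to [0, 1] via ``(x - min) / (max - min)``.

    Raises :class:`DegenerateImageError` for spatially constant input rather
    than dividing by zero.
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot normalize an empty image")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise DegenerateImageError(
            f"constant image (min == max == {lo}) cannot be min-max rescaled")
    out = (arr - lo) / (hi - lo)
    if out.ndim == 2:
        out = np.repeat(out[:, :, None], 3, axis=2)
    return NormalizedImage(pixels=out, source_id=source_id)


def prepare_image(image: np.ndarray, source_id: str = "",
                  size: tuple[int, int] = (256, 256)) -> NormalizedImage:
    """Resize to ``size`` (bilinear), replicate grayscale to 3 channels, and
    min-max normalize — the standard ingestion path for raw images."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape[:2] != tuple(size):
        arr = _sk_resize(arr, (*size, arr.shape[2]), order=1,
                         preserve_range=True, anti_aliasing=False)
    return normalize_minmax(arr, source_id=source_id)


# ---------------------------------------------------------------------------
# stationary wavelet transform


def swt_decompose(image: NormalizedImage, levels: int = 3,
                  wavelet: str = "db2") -> SwtStack:
    """3-channel 2-D stationary wavelet decomposition.

    Each channel is transformed independently; coefficients are stacked into
    ``(h, w, 3, levels)`` arrays with level 1 at index 0.  Spatial dimensions
    not divisible by ``2**levels`` are reflect-padded (recorded in ``pad``)
    so the undecimated transform is defined; the default 256 x 256 path needs
    no padding.
    """
    if levels < 1:
        raise ValidationError(f"levels must be >= 1, got {levels}")
    if wavelet not in pywt.wavelist(kind="discrete"):
        raise ConfigurationError(f"unsupported wavelet {wavelet!r}")
    px = image.pixels
    h, w, _ = px.shape
    mult = 2 ** levels
    pad_h = (-h) % mult
    pad_w = (-w) % mult
    pad = ((0, pad_h), (0, pad_w))
    if pad_h or pad_w:
        px = np.pad(px, (*pad, (0, 0)), mode="reflect")
    hp, wp = px.shape[:2]
    app = np.empty((hp, wp, 3, levels))
    ver = np.empty_like(app)
    hor = np.empty_like(app)
    dia = np.empty_like(app)
    for c in range(3):
        # pywt returns the coarsest level first; reverse to level-1-first
        coeffs = pywt.swt2(px[:, :, c], wavelet, level=levels)
        for li, (cA, (cH, cV, cD)) in enumerate(reversed(coeffs)):
            app[:, :, c, li] = cA
            hor[:, :, c, li] = cH
            ver[:, :, c, li] = cV
            dia[:, :, c, li] = cD
    return SwtStack(app=app, ver=ver, hor=hor, dia=dia, wavelet_name=wavelet,
                    source_id=image.source_id, pad=pad, original_shape=(h, w))


def swt_reconstruct(stack: SwtStack) -> np.ndarray:
    """Inverse stationary wavelet transform; crops any decomposition padding."""
    n = stack.levels
    hp, wp = stack.app.shape[:2]
    out = np.empty((hp, wp, 3))
    for c in range(3):
        coeffs = [
            (stack.app[:, :, c, li],
             (stack.hor[:, :, c, li], stack.ver[:, :, c, li], stack.dia[:, :, c, li]))
            for li in range(n - 1, -1, -1)
        ]
        out[:, :, c] = pywt.iswt2(coeffs, stack.wavelet_name)
    if stack.original_shape is not None:
        h, w = stack.original_shape
        out = out[:h, :w, :]
    return out


def swt_augment_images(image: NormalizedImage, levels: int = 3,
                       wavelet: str = "db2") -> list[NormalizedImage]:
    """One derived image per decomposition level: the approximation plane,
    min-max rescaled back to [0, 1].

    The detail planes are near-zero-mean and uninformative as standalone
    images; the low-frequency approximation retains the content, so it is
    the per-level augmentation product.  A constant input has constant
    approximations and raises :class:`DegenerateImageError`.
    """
    stack = swt_decompose(image, levels=levels, wavelet=wavelet)
    h, w = stack.original_shape
    out = []
    for li in range(levels):
        plane = stack.app[:h, :w, :, li]
        out.append(normalize_minmax(plane, source_id=f"{image.source_id}|L{li + 1}"))
    return out


# ---------------------------------------------------------------------------
# geometric augmentation


def _warp(px: np.ndarray, matrix: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Affine warp of (h, w, 3) pixels, bilinear, zero fill, clipped to [0,1].

    ``matrix``/``offset`` map output pixel coordinates to input coordinates.
    """
    m3 = np.eye(3)
    m3[:2, :2] = matrix
    off3 = np.array([offset[0], offset[1], 0.0])
    out = ndimage.affine_transform(px, m3, offset=off3, order=1,
                                   mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0)


def translate_image(image: NormalizedImage, dy: float, dx: float) -> NormalizedImage:
    """Shift content by (+dy, +dx) pixels: a pixel at (r, c) moves to
    (r + dy, c + dx).  Bilinear, zero fill."""
    out = _warp(image.pixels, np.eye(2), np.array([-dy, -dx]))
    return NormalizedImage(out, source_id=f"{image.source_id}|translate")


def rotate_image(image: NormalizedImage, angle_deg: float) -> NormalizedImage:
    """Rotate about the image center by ``angle_deg``.  Bilinear, zero fill."""
    h, w, _ = image.pixels.shape
    a = math.radians(angle_deg)
    # inverse rotation in (row, col) coordinates about the center
    rot = np.array([[math.cos(a), math.sin(a)], [-math.sin(a), math.cos(a)]])
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - rot @ center
    out = _warp(image.pixels, rot, offset)
    return NormalizedImage(out, source_id=f"{image.source_id}|rotate")


def shear_image(image: NormalizedImage, angle_deg: float) -> NormalizedImage:
    """Horizontal shear by ``angle_deg`` about the image center."""
    h, w, _ = image.pixels.shape
    s = math.tan(math.radians(angle_deg))
    shear = np.array([[1.0, 0.0], [s, 1.0]])  # inverse map: col += s * row
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - shear @ center
    out = _warp(image.pixels, shear, offset)
    return NormalizedImage(out, source_id=f"{image.source_id}|shear")


def geometric_variants(image: NormalizedImage, params: AugmentationParams,
                       rng: np.random.Generator) -> list[NormalizedImage]:
    """Three derived images: one random translation, one random rotation,
    one random shear, each drawn independently from the parameter ranges."""
    dy = rng.uniform(*params.translation_range)
    dx = rng.uniform(*params.translation_range)
    rot = rng.uniform(*params.rotation_range)
    shr = rng.uniform(*params.shear_range)
    return [
        translate_image(image, dy, dx),
        rotate_image(image, rot),
        shear_image(image, shr),
    ]


# ---------------------------------------------------------------------------
# training-set augmentation (x9) and splitting


def _as_normalized(img: np.ndarray, source_id: str) -> NormalizedImage:
    arr = np.asarray(img, dtype=float)
    if arr.max() > 1.0 or arr.min() < 0.0:
        return normalize_minmax(arr, source_id=source_id)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return NormalizedImage(arr, source_id=source_id)


def iter_augmented(train: ImageSet, params: AugmentationParams,
                   levels: int = 3, wavelet: str = "db2",
                   ) -> Iterator[tuple[np.ndarray, str, str]]:
    """Lazily yield ``(pixels, label, provenance_id)`` for the x9 augmentation.

    For each input image the three per-level approximation images each get
    the three geometric operations, so nine augmented images replace one
    source.  Provenance ids are ``source|L<level>|<transform>``.
    """
    if len(train) == 0:
        raise ValidationError("training set is empty")
    rng = np.random.default_rng(child_seed(params.seed, "augment"))
    for img, label, sid in zip(train.images, train.labels, train.ids):
        norm = _as_normalized(img, sid)
        for level_img in swt_augment_images(norm, levels=levels, wavelet=wavelet):
            for variant in geometric_variants(level_img, params, rng):
                yield variant.pixels, label, variant.source_id


def augment_training_set(train: ImageSet, params: AugmentationParams,
                         levels: int = 3, wavelet: str = "db2") -> ImageSet:
    """Materialized nine-fold augmentation of *train* (see :func:`iter_augmented`)."""
    images, labels, ids = [], [], []
    for px, label, sid in iter_augmented(train, params, levels=levels, wavelet=wavelet):
        images.append(px.astype(np.float32))
        labels.append(label)
        ids.append(sid)
    return ImageSet(images=images, labels=labels, ids=ids)


def split_sizes(m: int, ratios: tuple[float, float, float] = (0.60, 0.25, 0.15)
                ) -> tuple[int, int, int]:
    """Per-class split sizes: train = floor(r_train*m), test = floor(r_test*m),
    validation takes the remainder (4094 -> 2456/1024/614)."""
    r_train, _, r_test = ratios
    n_train = math.floor(r_train * m)
    n_test = math.floor(r_test * m)
    n_val = m - n_train - n_test
    return n_train, n_val, n_test


def split_dataset(data: ImageSet, spec: SplitSpec
                  ) -> tuple[ImageSet, ImageSet, ImageSet]:
    """Seeded stratified split into (train, validation, test).

    Each class is shuffled independently and cut by the floor rule of
    :func:`split_sizes`; subsets are disjoint and their union is the input.
    """
    rng = np.random.default_rng(child_seed(spec.seed, "split"))
    train_idx: list[int] = []
    val_idx: list[int] = []
    test_idx: list[int] = []
    labels = np.asarray(data.labels)
    for label in data.classes:
        cls_idx = np.flatnonzero(labels == label)
        m = cls_idx.size
        if m < 3:
            raise ValidationError(
                f"class {label!r} has only {m} items; need >= 3 to split")
        perm = rng.permutation(m)
        n_train, n_val, n_test = split_sizes(m, spec.ratios)
        shuffled = cls_idx[perm]
        train_idx.extend(shuffled[:n_train])
        val_idx.extend(shuffled[n_train:n_train + n_val])
        test_idx.extend(shuffled[n_train + n_val:])
    return data.subset(train_idx), data.subset(val_idx), data.subset(test_idx)
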
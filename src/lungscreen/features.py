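"""Pluggable 1000-dimensional feature extractors and feature fusion.

The screening scheme treats its deep feature generators as black boxes: each
maps one image to a fixed-length real vector (1000 dims in the reference
configuration), and the per-extractor outputs are concatenated into a single
fused matrix — three 1000-wide extractors give the 3000-column representation
consumed by the selectors.  The :class:`FeatureExtractor` contract makes any
such map pluggable; adapters for ImageNet-pretrained networks can implement
it, but the core library never requires their weights.

:func:`standin_extractor` is a deterministic, desk-scale extractor built from
multi-scale image statistics (patch-grid means/variances plus stationary-
wavelet subband energies) projected to the target dimensionality by a fixed
seeded random matrix.  It is synthetic — a stand-in for a pretrained network,
not an approximation of one — but it yields linearly separable features on
the texture fixtures, which is all the downstream stages need.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pywt
from skimage.transform import resize as _sk_resize

from .containers import FeatureMatrix, ImageSet
from .errors import AlignmentError, ContractViolationError

Vector = np.ndarray


@dataclass
class FeatureExtractor:
    """Contract for a deterministic image -> feature-vector map."""

    name: str
    apply: Callable[[np.ndarray], Vector]
    output_dim: int = 1000
    input_size: tuple[int, int, int] = (256, 256, 3)


def _to_float_rgb(image: np.ndarray, size: tuple[int, int, int]) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.max() > 1.0:
        arr = arr / 255.0
    if arr.shape != tuple(size):
        arr = _sk_resize(arr, size, order=1, preserve_range=True,
                         anti_aliasing=False)
    return arr


def extract_features(extractor: FeatureExtractor, images: ImageSet) -> FeatureMatrix:
    """Apply *extractor* to every image (resized to its input size).

    Row ``i`` of the result is ``extractor.apply(resize(image_i))``; the
    block map records a single block named after the extractor.
    """
    rows = np.empty((len(images), extractor.output_dim))
    for i, img in enumerate(images.images):
        vec = np.asarray(extractor.apply(_to_float_rgb(img, extractor.input_size)),
                         dtype=float).ravel()
        if vec.size != extractor.output_dim:
            raise ContractViolationError(
                f"extractor {extractor.name!r} returned {vec.size} values, "
                f"declared output_dim is {extractor.output_dim}")
        rows[i] = vec
    return FeatureMatrix(
        values=rows,
        labels=np.asarray(images.labels),
        block_map=[(extractor.name, 0, extractor.output_dim)],
        sample_ids=list(images.ids),
    )


def merge_features(parts: list[FeatureMatrix]) -> FeatureMatrix:
    """Horizontally concatenate per-extractor matrices in the given order.

    All parts must agree on sample count, order, and labels; the merged
    block map records each source's column range so selected indices remain
    attributable to their extractor.
    """
    if not parts:
        raise AlignmentError("merge_features needs at least one part")
    if len(parts) == 1:
        return parts[0]
    first = parts[0]
    for p in parts[1:]:
        if p.n_samples != first.n_samples:
            raise AlignmentError(
                f"row-count mismatch: {p.n_samples} vs {first.n_samples}")
        if not np.array_equal(p.labels, first.labels):
            raise AlignmentError("label vectors differ between parts")
        if p.sample_ids != first.sample_ids:
            raise AlignmentError("sample order differs between parts")
    block_map: list[tuple[str, int, int]] = []
    pos = 0
    for p in parts:
        for name, start, end in p.block_map:
            block_map.append((name, pos + start, pos + end))
        pos += p.n_features
    return FeatureMatrix(
        values=np.hstack([p.values for p in parts]),
        labels=first.labels.copy(),
        block_map=block_map,
        sample_ids=list(first.sample_ids),
    )


#: radial frequency band edges (cycles/pixel) for the spectral profile
_BAND_EDGES = np.array([0.01, 0.02, 0.04, 0.08, 0.16, 0.32, 0.50])


def _raw_statistics(img: np.ndarray, grid: int = 4, swt_levels: int = 2) -> Vector:
    """Multi-scale statistics of one (h, w, 3) float image.

    Per channel: center-disk intensity moments and an 8-bin histogram
    (robust to the zero-filled borders that geometric augmentation leaves),
    a radial power-spectrum profile of the Hann-windowed plane (translation-
    and rotation-invariant texture frequency signature), stationary-wavelet
    subband energies, and a coarse ``grid x grid`` patch-mean map for
    residual spatial layout.
    """
    h, w, _ = img.shape
    feats: list[float] = []
    win = np.outer(np.hanning(h), np.hanning(w))
    yy, xx = np.mgrid[0:h, 0:w]
    disk = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2) <= 0.45 * min(h, w)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    fr = np.hypot(fy, fx)
    band_masks = [(fr >= lo) & (fr < hi)
                  for lo, hi in zip(_BAND_EDGES[:-1], _BAND_EDGES[1:])]
    ph, pw = max(1, h // grid), max(1, w // grid)
    mult = 2 ** swt_levels
    hc, wc = (h // mult) * mult, (w // mult) * mult
    for c in range(3):
        plane = img[:, :, c]
        dpx = plane[disk]
        feats.extend([dpx.mean(), dpx.std()])
        feats.extend(np.histogram(dpx, bins=8, range=(0.0, 1.0), density=True)[0])
        power = np.abs(np.fft.fft2((plane - plane.mean()) * win)) ** 2
        total = power.sum() + 1e-12
        feats.extend(np.log(power[m].sum() / total + 1e-9) for m in band_masks)
        patches = plane[:grid * ph, :grid * pw].reshape(grid, ph, grid, pw)
        feats.extend(patches.mean(axis=(1, 3)).ravel())
        if hc >= mult and wc >= mult:
            coeffs = pywt.swt2(plane[:hc, :wc], "db2", level=swt_levels)
            for cA, (cH, cV, cD) in coeffs:
                feats.extend([np.mean(cA ** 2), np.mean(cH ** 2),
                              np.mean(cV ** 2), np.mean(cD ** 2)])
    return np.asarray(feats, dtype=float)


def standin_extractor(seed: int, name: str | None = None,
                      output_dim: int = 1000,
                      input_size: tuple[int, int, int] = (256, 256, 3),
                      ) -> FeatureExtractor:
    """Deterministic desk-scale extractor (synthetic stand-in).

    The raw statistic vector of :func:`_raw_statistics` is projected to
    ``output_dim`` dimensions by a fixed Gaussian random matrix drawn once
    from ``seed``; two extractors with different seeds therefore produce
    different (near-orthogonal) feature spaces over the same statistics.
    """
    if name is None:
        name = f"standin:{seed}"
    proj: dict[int, np.ndarray] = {}

    def apply(img: np.ndarray) -> Vector:
        stats = _raw_statistics(img)
        key = stats.size
        if key not in proj:
            rng = np.random.default_rng(seed)
            proj[key] = rng.standard_normal((key, output_dim)) / np.sqrt(key)
        return stats @ proj[key]

    return FeatureExtractor(name=name, apply=apply, output_dim=output_dim,
                            input_size=input_size)


def default_extractors(master_seed: int = 0, n: int = 3,
                       output_dim: int = 1000) -> list[FeatureExtractor]:
    """The reference bank: *n* independent stand-in extractors."""
    return [standin_extractor(seed=master_seed * 1000 + k,
                              name=f"standin:{chr(ord('A') + k)}",
                              output_dim=output_dim)
            for k in range(n)]
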
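"""In-memory containers shared by every stage: labeled image collections and
block-structured feature matrices.

``ImageSet`` is an ordered collection of images with class labels and
provenance tags.  ``FeatureMatrix`` is the ``n_samples x n_features`` fused
representation: a dense real matrix plus a label vector, per-sample ids, and
a ``block_map`` recording which extractor produced which column range, so a
selected feature index is always attributable to its source extractor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError


@dataclass
class ImageSet:
    """Ordered, labeled image collection.

    Parameters
    ----------
    images : list of ndarray
        Each image is ``(h, w, 3)``; dtype may be uint8 (raw fixtures,
        values in [0, 255]) or float (normalized, values in [0, 1]).
    labels : list of str
        Class label per image.
    ids : list of str
        Provenance tag per image (source id, possibly extended with the
        augmentation level/transform that produced it).
    """

    images: list[np.ndarray]
    labels: list[str]
    ids: list[str]

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.labels) == len(self.ids)):
            raise ValidationError(
                f"images/labels/ids lengths differ: "
                f"{len(self.images)}/{len(self.labels)}/{len(self.ids)}"
            )

    def __len__(self) -> int:
        return len(self.images)

    @property
    def classes(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        return list(dict.fromkeys(self.labels))

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    def subset(self, indices) -> "ImageSet":
        idx = list(indices)
        return ImageSet(
            images=[self.images[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            ids=[self.ids[i] for i in idx],
        )


@dataclass
class FeatureMatrix:
    """Dense feature matrix with label vector and column-block provenance.

    ``block_map`` is an ordered list of ``(extractor_name, start, end)``
    half-open column ranges that partition ``[0, n_features)``.
    """

    values: np.ndarray
    labels: np.ndarray
    block_map: list[tuple[str, int, int]] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {self.values.shape}")
        if self.labels.shape[0] != self.values.shape[0]:
            raise AlignmentError(
                f"label count {self.labels.shape[0]} != sample count {self.values.shape[0]}"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("feature values contain NaN or Inf")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:06d}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise AlignmentError("sample_ids length does not match sample count")
        if not self.block_map:
            self.block_map = [("features", 0, self.values.shape[1])]
        self._check_blocks()

    def _check_blocks(self) -> None:
        pos = 0
        for name, start, end in self.block_map:
            if start != pos or end < start:
                raise ValidationError(f"block_map does not partition columns at {name!r}")
            pos = end
        if pos != self.values.shape[1]:
            raise ValidationError(
                f"block_map covers {pos} columns but matrix has {self.values.shape[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def block(self, name: str) -> np.ndarray:
        """Column slice belonging to extractor *name*."""
        for bname, start, end in self.block_map:
            if bname == name:
                return self.values[:, start:end]
        raise KeyError(f"no block named {name!r}")

    def select_columns(self, indices) -> "FeatureMatrix":
        """New matrix restricted to *indices* (block provenance collapses)."""
        idx = np.asarray(list(indices), dtype=int)
        return FeatureMatrix(
            values=self.values[:, idx],
            labels=self.labels.copy(),
            block_map=[("selected", 0, idx.size)],
            sample_ids=list(self.sample_ids),
            metadata={**self.metadata, "selected_from": self.block_map,
                      "selected_indices": idx.tolist()},
        )

    # -- serialization --------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """`sample_id,label,f0..f{d-1}` layout, full float precision."""
        df = pd.DataFrame(self.values, columns=[f"f{j}" for j in range(self.n_features)])
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c not in ("sample_id", "label")]
        return cls(
            values=df[cols].to_numpy(dtype=float),
            labels=df["label"].astype(str).to_numpy(),
            sample_ids=[str(s) for s in df["sample_id"]] if "sample_id" in df else [],
        )

    def save(self, path: str | Path) -> None:
        """Compact binary container (npz) with a JSON sidecar for the block map."""
        path = Path(path)
        np.savez_compressed(
            path,
            values=self.values,
            labels=self.labels.astype(str),
            sample_ids=np.array(self.sample_ids, dtype=str),
        )
        sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".npz" \
            else path.with_suffix(".json")
        sidecar.write_text(json.dumps(
            {"block_map": [list(b) for b in self.block_map], "metadata": self.metadata},
            indent=2, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        if not path.exists() and path.with_suffix(".npz").exists():
            path = path.with_suffix(".npz")
        with np.load(path, allow_pickle=False) as z:
            values = z["values"]
            labels = z["labels"]
            sample_ids = [str(s) for s in z["sample_ids"]]
        sidecar = path.with_suffix(".json")
        block_map: list[tuple[str, int, int]] = []
        metadata: dict = {}
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            block_map = [tuple(b) for b in meta.get("block_map", [])]
            metadata = meta.get("metadata", {})
        return cls(values=values, labels=labels, block_map=block_map,
                   sample_ids=sample_ids, metadata=metadata)
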
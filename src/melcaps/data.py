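"""Labeled image sets with provenance, plus PNG/CSV-manifest round-trips.

Labels follow the study convention: 0 = nevus (normal), 1 = melanoma.
Every image carries its own identifier and an ``origin_id`` pointing at the
source image it was derived from; for original images the two coincide.
The on-disk layout is one PNG per image plus a ``manifest.csv`` with
columns ``image_path,label,origin_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = ["LabeledImageSet"]


@dataclass
class LabeledImageSet:
    images: list[np.ndarray]
    labels: np.ndarray
    ids: list[str] = field(default_factory=list)
    origin_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.ids:
            self.ids = [f"img_{i:05d}" for i in range(len(self.images))]
        if not self.origin_ids:
            self.origin_ids = list(self.ids)
        if not (len(self.images) == len(self.labels) == len(self.ids) == len(self.origin_ids)):
            raise ValueError("images, labels, ids and origin_ids must have equal length")
        if len(self.labels) and not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary (0 = nevus, 1 = melanoma)")

    def __len__(self) -> int:
        return len(self.images)

    def class_counts(self) -> tuple[int, int]:
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())

    def subset(self, index) -> "LabeledImageSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return LabeledImageSet(
            images=[self.images[i] for i in index],
            labels=self.labels[index],
            ids=[self.ids[i] for i in index],
            origin_ids=[self.origin_ids[i] for i in index],
        )

    def stack(self) -> np.ndarray:
        """All images as one (N, H, W, 3) float array (requires equal sizes)."""
        return np.stack(self.images)

    # -- disk round-trip ---------------------------------------------------
    def save(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for img, lab, iid, oid in zip(self.images, self.labels, self.ids, self.origin_ids):
            path = out_dir / f"{iid}.png"
            iio.imwrite(path, (np.clip(img, 0, 1) * 255).round().astype(np.uint8))
            rows.append({"image_path": path.name, "label": int(lab), "origin_id": oid})
        manifest = out_dir / "manifest.csv"
        pd.DataFrame(rows).to_csv(manifest, index=False)
        return manifest

    @classmethod
    def load(cls, manifest_path) -> "LabeledImageSet":
        manifest_path = Path(manifest_path)
        df = pd.read_csv(manifest_path)
        base = manifest_path.parent
        images, ids = [], []
        for p in df["image_path"]:
            images.append(iio.imread(base / p).astype(float) / 255.0)
            ids.append(Path(p).stem)
        return cls(
            images=images,
            labels=df["label"].to_numpy(),
            ids=ids,
            origin_ids=[str(o) for o in df["origin_id"]],
        )
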
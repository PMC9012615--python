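"""Labelled beat-image collections tagged with their interpatient partition."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoding import ScalogramImage
from .io import TARGET_CLASSES

__all__ = ["BeatDataset"]


@dataclass
class BeatDataset:
    """Images + labels for one partition (DS1 train / DS2 test).

    `augmented` records whether class balancing has been applied; the
    evaluation protocol requires it to stay False for DS2.
    """

    images: np.ndarray  # (n, 3, H, W) float32
    labels: np.ndarray  # (n,) unicode, values in TARGET_CLASSES
    partition: str  # "DS1" | "DS2"
    augmented: bool = False
    provenance: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype="U1")
        if self.images.ndim != 4 or self.images.shape[0] != self.labels.shape[0]:
            raise ValueError("images must be (n, 3, H, W) aligned with labels")
        if self.partition not in ("DS1", "DS2"):
            raise ValueError("partition must be 'DS1' or 'DS2'")
        bad = set(self.labels) - set(TARGET_CLASSES)
        if bad:
            raise ValueError(f"labels outside {TARGET_CLASSES}: {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.images.shape[0])

    @classmethod
    def from_images(cls, images: list[ScalogramImage], partition: str,
                    augmented: bool = False) -> "BeatDataset":
        if not images:
            raise ValueError("empty image list")
        pixels = np.stack([im.pixels for im in images])
        labels = np.array([im.label for im in images])
        prov = [(im.record_id, im.r_current, im.augmentation) for im in images]
        return cls(images=pixels, labels=labels, partition=partition,
                   augmented=augmented, provenance=prov)

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in TARGET_CLASSES}

    def save(self, path: str | Path) -> None:
        """Serialise as `<path>.npz` (arrays) + `<path>.json` (manifest)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path.with_suffix(".npz"),
                            images=self.images, labels=self.labels)
        manifest = {"partition": self.partition, "augmented": self.augmented,
                    "n": len(self), "class_counts": self.class_counts(),
                    "provenance": [list(p) for p in self.provenance]}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "BeatDataset":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        manifest = json.loads(path.with_suffix(".json").read_text())
        return cls(images=arrays["images"], labels=arrays["labels"],
                   partition=manifest["partition"],
                   augmented=manifest["augmented"],
                   provenance=[tuple(p) for p in manifest["provenance"]])
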
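"""Class balancing by pixel-shift replication of training-beat images.

Minority classes in the training partition are replicated by small
left/right/up/down translations of the 2-D beat image (zero-filled at
the vacated border).  Shifting the image rather than the 1-D trace
preserves the beat's time-domain content while still diversifying the
training set.  The default per-class factors (N x1, S x20, V x10,
F x20) are the ones forced by the published pre/post balancing counts
of the interpatient training set.  The test partition is never
augmented; :func:`balance_dataset` enforces that protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import BeatDataset
from .io import TARGET_CLASSES

__all__ = ["AugmentationPlan", "shift_image", "balance_dataset", "default_shift_grid"]


def default_shift_grid() -> list[tuple[int, int]]:
    """Identity plus +-{2,4,6,8,10}-pixel moves alternating along x and y."""
    grid: list[tuple[int, int]] = [(0, 0)]
    for m in (2, 4, 6, 8, 10):
        grid += [(m, 0), (-m, 0), (0, m), (0, -m)]
    return grid


@dataclass
class AugmentationPlan:
    """Per-class replication factors and the ordered shift inventory."""

    factors: dict[str, int] = field(
        default_factory=lambda: {"N": 1, "S": 20, "V": 10, "F": 20})
    shift_grid: list[tuple[int, int]] = field(default_factory=default_shift_grid)

    def __post_init__(self):
        for c in TARGET_CLASSES:
            if self.factors.get(c, 1) < 1:
                raise ValueError(f"factor for class {c} must be >= 1")
        self.factors = {c: int(self.factors.get(c, 1)) for c in TARGET_CLASSES}
        if self.shift_grid[0] != (0, 0):
            raise ValueError("shift_grid must start with the identity (0, 0)")
        if len(set(self.shift_grid)) != len(self.shift_grid):
            raise ValueError("shift_grid entries must be distinct")
        if len(self.shift_grid) < max(self.factors.values()):
            raise ValueError("shift_grid shorter than the largest factor")

    def projected_counts(self, counts: dict[str, int]) -> dict[str, int]:
        """Post-balancing class counts implied by the plan: factor(c) * n_c."""
        return {c: self.factors[c] * int(counts.get(c, 0)) for c in TARGET_CLASSES}


def shift_image(pixels: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate (C, H, W) pixels by dx columns / dy rows, zero-filling.

    Positive dx moves content right, positive dy moves it down.
    """
    c, h, w = pixels.shape
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError(f"shift ({dx}, {dy}) exceeds image size {h}x{w}")
    out = np.zeros_like(pixels)
    src_y = slice(max(0, -dy), h - max(0, dy))
    dst_y = slice(max(0, dy), h - max(0, -dy))
    src_x = slice(max(0, -dx), w - max(0, dx))
    dst_x = slice(max(0, dx), w - max(0, -dx))
    out[:, dst_y, dst_x] = pixels[:, src_y, src_x]
    return out


def balance_dataset(dataset: BeatDataset, plan: AugmentationPlan | None = None) -> BeatDataset:
    """Replicate every class-c image into factor(c) copies (original + shifts).

    Only the training partition may be balanced; calling this on a DS2
    dataset raises, guarding the interpatient evaluation protocol.
    """
    plan = plan or AugmentationPlan()
    if dataset.partition != "DS1":
        raise ValueError("augmentation is restricted to the DS1 training set")
    if dataset.augmented:
        raise ValueError("dataset is already augmented")
    images, labels, prov = [], [], []
    have_prov = len(dataset.provenance) == len(dataset)
    for i in range(len(dataset)):
        label = str(dataset.labels[i])
        factor = plan.factors[label]
        base = dataset.images[i]
        rec, r, _ = dataset.provenance[i] if have_prov else ("", -1, "original")
        for j in range(factor):
            dx, dy = plan.shift_grid[j]
            images.append(base if (dx, dy) == (0, 0) else shift_image(base, dx, dy))
            labels.append(label)
            prov.append((rec, r, "original" if (dx, dy) == (0, 0)
                         else f"shift({dx},{dy})"))
    return BeatDataset(images=np.stack(images), labels=np.array(labels),
                       partition="DS1", augmented=True, provenance=prov)
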
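"""R-peak-anchored heartbeat segmentation.

Each annotated beat is cut out of the record using only the R peaks of
its two neighbours: the window is the central three quarters of the
interval [R_previous, R_last], so its length is

    E_beat = round(3 * (R_last - R_previous) / 4)

and one eighth of the R-R span is trimmed from each end.  Beats without
both neighbours (the first and last of a record) are not segmented, and
windows that would run past the signal are dropped rather than padded.
Because the window length follows the local heart rate, beats come out
with unequal lengths; the time-frequency encoding step later maps them
all to a fixed image size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ECGRecord, map_symbol_to_aami

__all__ = ["Beat", "segment_beats", "beat_window"]


@dataclass
class Beat:
    """One segmented heartbeat."""

    record_id: str
    r_current: int
    start: int  # half-open window [start, end)
    end: int
    label: str  # AAMI class, one of N/S/V/F
    samples: np.ndarray

    @property
    def length(self) -> int:
        return self.end - self.start


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def beat_window(r_previous: int, r_last: int) -> tuple[int, int]:
    """Window [start, end) covering the central 3/4 of [r_previous, r_last]."""
    span = r_last - r_previous
    length = _round_half_up(3.0 * span / 4.0)
    start = r_previous + _round_half_up(span / 8.0)
    return start, start + length


def segment_beats(record: ECGRecord, window_mode: str = "interval_center",
                  drop_q: bool = True) -> list[Beat]:
    """Segment every interior annotated beat of `record`.

    `window_mode='interval_center'` places the window as the central 3/4
    of the neighbouring R-R span; `'r_centered'` centres a window of the
    same length on the beat's own R peak.  Records with fewer than three
    annotations yield no beats.  Q-class beats are skipped when `drop_q`
    (the classifier covers N/S/V/F only).
    """
    if window_mode not in ("interval_center", "r_centered"):
        raise ValueError(f"unknown window_mode {window_mode!r}")
    ann = record.annotations
    idx = [i for i, _ in ann]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValueError("annotations must be strictly increasing")
    n = len(record.samples)
    beats: list[Beat] = []
    for k in range(1, len(ann) - 1):
        r_prev, _ = ann[k - 1]
        r_cur, symbol = ann[k]
        r_last, _ = ann[k + 1]
        label = map_symbol_to_aami(symbol)
        if drop_q and label == "Q":
            continue
        start, end = beat_window(r_prev, r_last)
        if window_mode == "r_centered":
            length = end - start
            start = r_cur - length // 2
            end = start + length
        if start < 0 or end > n or end <= start:
            continue
        beats.append(Beat(record_id=record.record_id, r_current=r_cur,
                          start=start, end=end, label=label,
                          samples=record.samples[start:end].copy()))
    return beats
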
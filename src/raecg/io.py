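"""ECG record I/O, AAMI beat-class mapping and the interpatient split.

The MIT-BIH arrhythmia database annotates every heartbeat with a
single-character beat code at the R-peak sample.  Following the AAMI
EC57 standard those codes collapse into five superclasses:

====  =======================================================
N     normal, bundle-branch block, atrial/nodal escape
S     supraventricular ectopic (atrial/nodal premature)
V     ventricular ectopic (PVC, ventricular escape)
F     fusion of ventricular and normal
Q     paced, fusion of paced and normal, unclassifiable
====  =======================================================

Interpatient evaluation uses the de Chazal protocol: the four paced
records (102, 104, 107, 217) are excluded and the remaining 44 records
are divided into disjoint train (DS1) and test (DS2) sets so no
patient contributes beats to both.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import wfdb_io

__all__ = [
    "ECGRecord", "read_record", "map_symbol_to_aami", "get_split",
    "AAMI_CLASSES", "TARGET_CLASSES", "BEAT_SYMBOLS", "DS1_RECORDS",
    "DS2_RECORDS", "EXCLUDED_RECORDS", "MITDB_RECORDS",
]

AAMI_CLASSES = ("N", "S", "V", "F", "Q")
#: classes the classifier predicts; Q is mapped but dropped from datasets
TARGET_CLASSES = ("N", "S", "V", "F")

# MIT-BIH beat symbol -> AAMI superclass
_SYMBOL_TO_AAMI = {
    # normal + bundle-branch block + escape
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    # supraventricular ectopic
    "A": "S", "a": "S", "J": "S", "S": "S",
    # ventricular ectopic
    "V": "V", "E": "V",
    # fusion of ventricular and normal
    "F": "F",
    # paced / fusion-of-paced / unclassified
    "/": "Q", "f": "Q", "Q": "Q",
}
BEAT_SYMBOLS = frozenset(_SYMBOL_TO_AAMI)

DS1_RECORDS = frozenset({
    "101", "106", "108", "109", "112", "114", "115", "116", "118", "119",
    "122", "124", "201", "203", "205", "207", "208", "209", "215", "220",
    "223", "230",
})
DS2_RECORDS = frozenset({
    "100", "103", "105", "111", "113", "117", "121", "123", "200", "202",
    "210", "212", "213", "214", "219", "221", "222", "228", "231", "232",
    "233", "234",
})
EXCLUDED_RECORDS = frozenset({"102", "104", "107", "217"})
MITDB_RECORDS = frozenset(DS1_RECORDS | DS2_RECORDS | EXCLUDED_RECORDS)


@dataclass
class ECGRecord:
    """One annotated single-lead recording."""

    record_id: str
    sampling_rate: float
    samples: np.ndarray  # 1-D, physical units (mV)
    annotations: list[tuple[int, str]]  # (sample index, beat symbol), increasing

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        idx = [i for i, _ in self.annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotation indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= len(self.samples)):
            raise ValueError("annotation index outside the signal")

    @property
    def n_beats(self) -> int:
        return len(self.annotations)


def map_symbol_to_aami(symbol: str) -> str:
    """Map an MIT-BIH beat code to its AAMI superclass (N/S/V/F/Q)."""
    try:
        return _SYMBOL_TO_AAMI[symbol]
    except KeyError:
        raise KeyError(f"not a recognised MIT-BIH beat symbol: {symbol!r}") from None


def is_beat_symbol(symbol: str) -> bool:
    return symbol in _SYMBOL_TO_AAMI


def get_split(record_id: str) -> str:
    """Partition ('DS1' | 'DS2' | 'excluded') of a MIT-BIH record id."""
    record_id = str(record_id)
    if record_id in DS1_RECORDS:
        return "DS1"
    if record_id in DS2_RECORDS:
        return "DS2"
    if record_id in EXCLUDED_RECORDS:
        return "excluded"
    raise KeyError(f"unknown MIT-BIH record id: {record_id!r}")


def read_record(path: str | Path, channel: int = 0,
                annotation_suffix: str = ".atr") -> ECGRecord:
    """Read one WFDB record, keeping a single lead and beat annotations only.

    Non-beat annotations (rhythm changes, noise markers, comments, ...)
    are dropped.  Raises ``FileNotFoundError`` for missing files and
    ``ValueError`` for records without any beat annotation or with
    annotation indices outside the signal.
    """
    path = Path(path)
    sig = wfdb_io.read_wfdb(path)
    if not 0 <= channel < sig.signals.shape[1]:
        raise ValueError(f"record has {sig.signals.shape[1]} leads, "
                         f"channel {channel} requested")
    raw_ann = wfdb_io.read_annotations(path, suffix=annotation_suffix)
    beats = [(i, s) for i, s in raw_ann if is_beat_symbol(s)]
    if not beats:
        raise ValueError(f"record {path.name} has no beat annotations")
    n = sig.signals.shape[0]
    if beats[-1][0] >= n or beats[0][0] < 0:
        raise ValueError(f"record {path.name}: annotation index outside signal "
                         f"(signal length {n})")
    return ECGRecord(record_id=sig.record_name, sampling_rate=sig.fs,
                     samples=sig.signals[:, channel], annotations=beats)
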
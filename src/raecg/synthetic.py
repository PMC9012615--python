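"""Synthetic annotated single-lead ECG for download-free testing.

Beats are sums of Gaussian bumps (P wave, QRS complex, T wave) laid out
at randomised R-R intervals, with class-dependent morphology:

* **N** — full P-QRS-T complex, narrow QRS;
* **V** — wide, high-amplitude QRS, no P wave, inverted T;
* **F** — the average of the N and V morphologies (a fusion beat);
* **S** — near-normal morphology (slightly attenuated, earlier P) whose
  *preceding* R-R interval is shortened by 25-40%, encoding prematurity
  in timing the way real supraventricular ectopics do.  This mirrors
  the notorious N/S waveform confusability: the class signal is mostly
  rhythm, not shape.

The generator emulates the structure of an annotated arrhythmia record
(R-peak-aligned annotations, 360 Hz, millivolt amplitudes) but makes no
attempt to match real inter-lead morphology or noise spectra; it exists
to exercise segmentation, encoding, augmentation and training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import wfdb_io
from .io import ECGRecord

__all__ = ["SyntheticSpec", "make_synthetic_record", "write_fixture",
           "simulate_records", "CLASS_SYMBOLS"]

#: annotation symbol written for each AAMI class (A = atrial premature)
CLASS_SYMBOLS = {"N": "N", "S": "A", "V": "V", "F": "F"}

# Gaussian bumps per class: (amplitude mV, centre offset s, width s)
_N_BUMPS = [(0.12, -0.18, 0.025), (-0.10, -0.03, 0.010), (1.00, 0.0, 0.012),
            (-0.15, 0.03, 0.012), (0.30, 0.25, 0.050)]
_V_BUMPS = [(1.40, 0.0, 0.050), (-0.35, 0.30, 0.070)]
_S_BUMPS = [(0.08, -0.14, 0.022), (-0.09, -0.03, 0.010), (0.92, 0.0, 0.013),
            (-0.13, 0.03, 0.012), (0.27, 0.24, 0.048)]
_F_BUMPS = ([(0.5 * a, t, w) for a, t, w in _N_BUMPS]
            + [(0.5 * a, t, w) for a, t, w in _V_BUMPS])
_BUMPS = {"N": _N_BUMPS, "S": _S_BUMPS, "V": _V_BUMPS, "F": _F_BUMPS}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic record."""

    n_beats: int = 50
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"N": 1.0, "S": 0.0, "V": 0.0, "F": 0.0})
    mean_rr: float = 0.8  # seconds
    rr_jitter: float = 0.05  # fractional std of RR intervals
    sampling_rate: float = 360.0
    noise_sd: float = 0.02  # mV
    seed: int = 0
    record_id: str = "syn"

    def __post_init__(self):
        probs = np.array([self.class_mix.get(c, 0.0) for c in "NSVF"])
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("class_mix must be non-negative and sum to 1")
        if self.mean_rr <= 0 or self.sampling_rate <= 0:
            raise ValueError("mean_rr and sampling_rate must be positive")
        if self.n_beats < 3:
            raise ValueError("need at least 3 beats (edge beats are never "
                             "segmented)")
        if self.rr_jitter < 0 or self.noise_sd < 0:
            raise ValueError("rr_jitter and noise_sd must be non-negative")


def make_synthetic_record(spec: SyntheticSpec) -> ECGRecord:
    """Generate one annotated record, fully reproducible from `spec.seed`."""
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    classes = rng.choice(list("NSVF"), size=spec.n_beats,
                         p=[spec.class_mix.get(c, 0.0) for c in "NSVF"])
    rr = spec.mean_rr * (1.0 + spec.rr_jitter * rng.standard_normal(spec.n_beats))
    rr = np.maximum(rr, 0.3 * spec.mean_rr)
    # prematurity: an S beat arrives early, shortening its preceding RR
    for k in range(1, spec.n_beats):
        if classes[k] == "S":
            rr[k - 1] *= 1.0 - rng.uniform(0.25, 0.40)
    r_times = 1.0 + np.concatenate([[0.0], np.cumsum(rr[:-1])])  # 1 s lead-in
    duration = r_times[-1] + 1.0
    n = int(np.ceil(duration * fs))
    t = np.arange(n) / fs
    signal = np.zeros(n)
    for rt, cls in zip(r_times, classes):
        for amp, off, width in _BUMPS[cls]:
            centre = rt + off
            lo = max(0, int((centre - 5 * width) * fs))
            hi = min(n, int((centre + 5 * width) * fs) + 1)
            signal[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - centre) / width) ** 2)
    if spec.noise_sd > 0:
        signal += spec.noise_sd * rng.standard_normal(n)
    ann = [(int(round(rt * fs)), CLASS_SYMBOLS[c]) for rt, c in zip(r_times, classes)]
    return ECGRecord(record_id=spec.record_id, sampling_rate=fs,
                     samples=signal, annotations=ann)


def write_fixture(record: ECGRecord, path: str | Path) -> Path:
    """Write `record` as a WFDB fixture (.hea/.dat/.atr); returns the stem.

    Round-trips through :func:`raecg.io.read_record`: annotations exactly,
    samples to within one ADC quantisation step (gain 200 adu/mV).
    """
    path = Path(path)
    wfdb_io.write_wfdb(path, record.samples[:, None], record.sampling_rate,
                       descriptions=["MLII"])
    wfdb_io.write_annotations(path, record.annotations)
    return path


def simulate_records(out_dir: str | Path, n_records: int = 4,
                     beats_per_record: int = 120,
                     class_mix: dict[str, float] | None = None,
                     seed: int = 0, mean_rr: float = 0.8,
                     noise_sd: float = 0.02) -> dict[str, str]:
    """Write a directory of fixtures split alternately into DS1/DS2.

    Returns the record-id -> partition mapping (also saved as
    ``split.json`` beside the fixtures).
    """
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    class_mix = class_mix or {"N": 0.70, "S": 0.10, "V": 0.15, "F": 0.05}
    split: dict[str, str] = {}
    for i in range(n_records):
        rec_id = f"syn{i:02d}"
        spec = SyntheticSpec(n_beats=beats_per_record, class_mix=class_mix,
                             mean_rr=mean_rr, noise_sd=noise_sd,
                             seed=seed * 1000 + i, record_id=rec_id)
        write_fixture(make_synthetic_record(spec), out_dir / rec_id)
        split[rec_id] = "DS1" if i % 2 == 0 else "DS2"
    (out_dir / "split.json").write_text(json.dumps(split, indent=1))
    return split
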
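"""Minimal WFDB codec: headers, signal formats 16 and 212, MIT annotations.

Implements just enough of the WFDB physiologic-signal conventions to
round-trip this package's synthetic fixtures and to read MIT-BIH-style
records (``.hea`` header + ``.dat`` signal + ``.atr`` annotation files):

* header: record line ``name nsig fs nsamp`` plus one specification line
  per signal (``file fmt gain(baseline)/units adcres adczero init cksum
  blk description``),
* signal format 16 (little-endian int16, sample-interleaved) for writing
  and reading, format 212 (two 12-bit samples packed in 3 bytes) for
  reading the original MIT-BIH files,
* the MIT annotation format: 2-byte words holding a 6-bit type code and a
  10-bit time increment, with the SKIP/NUM/SUB/CHN/AUX pseudo-codes.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["read_wfdb", "write_wfdb", "read_annotations", "write_annotations",
           "ANNOTATION_SYMBOLS", "WFDBSignal"]

# MIT annotation code -> display symbol (ecgcodes convention)
ANNOTATION_SYMBOLS: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_CODES = {v: k for k, v in ANNOTATION_SYMBOLS.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class WFDBSignal:
    """Decoded record: physical units per channel plus header metadata."""

    record_name: str
    fs: float
    signals: np.ndarray  # (n_samples, n_sig), physical units
    units: list[str]
    descriptions: list[str]


def _parse_gain(field: str) -> tuple[float, int, str]:
    """Parse 'gain(baseline)/units' -> (gain, baseline, units)."""
    units = "mV"
    if "/" in field:
        field, units = field.split("/", 1)
    baseline = None
    if "(" in field:
        field, rest = field.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(field) if field else 200.0
    if gain == 0:
        gain = 200.0
    return gain, baseline, units


def read_wfdb(path: str | Path) -> WFDBSignal:
    """Read `<path>.hea` + its signal file; returns physical-unit samples."""
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing header file: {hea}")
    lines = [ln.strip() for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    name = rec_fields[0].split("/")[0]
    nsig = int(rec_fields[1])
    fs = float(rec_fields[2].split("/")[0]) if len(rec_fields) > 2 else 250.0
    nsamp = int(rec_fields[3]) if len(rec_fields) > 3 else 0

    specs = []
    for ln in lines[1 : 1 + nsig]:
        parts = ln.split()
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline, units = _parse_gain(parts[2]) if len(parts) > 2 else (200.0, None, "mV")
        adczero = int(parts[4]) if len(parts) > 4 else 0
        if baseline is None:
            baseline = adczero
        desc = " ".join(parts[8:]) if len(parts) > 8 else f"sig{len(specs)}"
        specs.append({"file": parts[0], "fmt": int(fmt), "gain": gain,
                      "baseline": baseline, "desc": desc, "units": units})

    datfile = path.parent / specs[0]["file"]
    if not datfile.exists():
        raise FileNotFoundError(f"missing signal file: {datfile}")
    raw = datfile.read_bytes()
    fmt = specs[0]["fmt"]
    if any(s["fmt"] != fmt for s in specs):
        raise ValueError("mixed signal formats are not supported")
    if fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2")
        adc = adc[: (len(adc) // nsig) * nsig].reshape(-1, nsig)
    elif fmt == 212:
        adc = _decode_212(raw, nsig)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    if nsamp:
        adc = adc[:nsamp]

    phys = np.empty(adc.shape, dtype=np.float64)
    for i, s in enumerate(specs):
        phys[:, i] = (adc[:, i].astype(np.float64) - s["baseline"]) / s["gain"]
    return WFDBSignal(record_name=name, fs=fs, signals=phys,
                      units=[s["units"] for s in specs],
                      descriptions=[s["desc"] for s in specs])


def _decode_212(raw: bytes, nsig: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    b = b[: (len(b) // 3) * 3].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    first = np.where(first > 2047, first - 4096, first)
    second = np.where(second > 2047, second - 4096, second)
    flat = np.empty(first.size * 2, dtype=np.int32)
    flat[0::2] = first
    flat[1::2] = second
    return flat[: (flat.size // nsig) * nsig].reshape(-1, nsig)


def write_wfdb(path: str | Path, signals: np.ndarray, fs: float,
               units: str = "mV", gain: float = 200.0,
               descriptions: list[str] | None = None) -> None:
    """Write a format-16 WFDB record (`.hea` + `.dat`) in physical units."""
    path = Path(path)
    signals = np.atleast_2d(np.asarray(signals, dtype=np.float64))
    nsamp, nsig = signals.shape  # (n_samples, n_sig) orientation
    adc = np.clip(np.rint(signals * gain), -32768, 32767).astype("<i2")
    datname = path.name + ".dat"
    descriptions = descriptions or [f"ch{i}" for i in range(nsig)]
    lines = [f"{path.name} {nsig} {fs:g} {nsamp}"]
    for i in range(nsig):
        cksum = int(np.sum(adc[:, i], dtype=np.int64) % 65536)
        lines.append(f"{datname} 16 {gain:g}(0)/{units} 16 0 "
                     f"{int(adc[0, i])} {cksum} 0 {descriptions[i]}")
    path.parent.mkdir(parents=True, exist_ok=True)
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    (path.parent / datname).write_bytes(adc.tobytes())


def read_annotations(path: str | Path, suffix: str = ".atr") -> list[tuple[int, str]]:
    """Decode an MIT-format annotation file -> [(sample_index, symbol), ...].

    Pseudo-annotations (SKIP/NUM/SUB/CHN/AUX) are consumed; unknown type
    codes are kept with symbol '?'.
    """
    path = Path(path).with_suffix(suffix)
    if not path.exists():
        raise FileNotFoundError(f"missing annotation file: {path}")
    raw = path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    n = len(raw)
    while i + 1 < n:
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            if i + 3 >= n:
                raise ValueError(f"truncated SKIP in {path}")
            hi = raw[i] | (raw[i + 1] << 8)
            lo = raw[i + 2] | (raw[i + 3] << 8)
            i += 4
            interval = (hi << 16) | lo
            if interval & 0x80000000:
                interval -= 1 << 32
            t += interval
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            i += delta + (delta & 1)
        else:
            t += delta
            out.append((t, ANNOTATION_SYMBOLS.get(code, "?")))
    return out


def write_annotations(path: str | Path, annotations: list[tuple[int, str]],
                      suffix: str = ".atr") -> None:
    """Encode [(sample_index, symbol), ...] as an MIT annotation file."""
    path = Path(path).with_suffix(suffix)
    buf = bytearray()
    prev = 0
    for sample, symbol in annotations:
        if symbol not in _SYMBOL_CODES:
            raise ValueError(f"no MIT annotation code for symbol {symbol!r}")
        delta = sample - prev
        if delta < 0:
            raise ValueError("annotation sample indices must be non-decreasing")
        if delta > 1023:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (_SYMBOL_CODES[symbol] << 10) | delta)
        prev = sample
    buf += b"\x00\x00"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_bytes(bytes(buf))
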
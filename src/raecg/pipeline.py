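"""End-to-end plumbing: records -> beats -> images -> datasets -> report.

These helpers glue the library modules together for the CLI, the
acceptance script and the test suite.  Everything is deterministic
given the run configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .augmentation import AugmentationPlan, balance_dataset
from .datasets import BeatDataset
from .encoding import CWTScalogram
from .io import ECGRecord, get_split, read_record
from .segmentation import segment_beats
from .training import EvalReport, RACNNClassifier, confusion_matrix

__all__ = ["RunConfig", "load_records", "build_datasets", "counts_table",
           "class_shares", "run_end_to_end"]


def class_shares(counts: dict[str, int]) -> dict[str, float]:
    """Percentage share of each class, rounded to 2 decimals."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return {c: round(100.0 * v / total, 2) for c, v in counts.items()}


@dataclass
class RunConfig:
    """All knobs of a pipeline run; unknown keys in a config file are errors."""

    seed: int = 0
    # synthetic-data generation
    n_records: int = 4
    beats_per_record: int = 120
    class_mix: dict = field(default_factory=lambda: {"N": 0.70, "S": 0.10,
                                                     "V": 0.15, "F": 0.05})
    noise_sd: float = 0.02
    mean_rr: float = 0.8
    # encoding
    wavelet: str = "morlet"
    n_scales: int = 64
    fmin: float = 0.5
    fmax: float = 45.0
    image_size: int = 224
    channel_mode: str = "replicate"
    # augmentation
    factors: dict = field(default_factory=lambda: {"N": 1, "S": 20,
                                                   "V": 10, "F": 20})
    # model / training
    stem_channels: int = 16
    groups: int = 2
    epochs: int = 60
    batch_size: int = 16
    initial_lr: float = 1e-3
    lr_step_epochs: int = 20
    lr_gamma: float = 0.1
    use_rblock: bool = True
    use_ablock: bool = True
    channel_att: bool = True
    spatial_att: bool = True
    top_skip: bool = True
    middle_layer: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def load_records(data_dir: str | Path,
                 records: list[str] | None = None) -> tuple[list[ECGRecord], dict[str, str]]:
    """Read every WFDB record under `data_dir` plus its partition map.

    The partition comes from ``split.json`` when present (synthetic
    fixtures), otherwise from the published interpatient split.
    """
    data_dir = Path(data_dir)
    split_file = data_dir / "split.json"
    split_map = json.loads(split_file.read_text()) if split_file.exists() else None
    stems = sorted(p.stem for p in data_dir.glob("*.hea"))
    if records:
        stems = [s for s in stems if s in set(records)]
    if not stems:
        raise FileNotFoundError(f"no WFDB records under {data_dir}")
    out, parts = [], {}
    for stem in stems:
        part = split_map.get(stem) if split_map else get_split(stem)
        if part == "excluded":
            continue
        out.append(read_record(data_dir / stem))
        parts[out[-1].record_id] = part
    return out, parts


def build_datasets(records: list[ECGRecord], partitions: dict[str, str],
                   encoder: CWTScalogram) -> tuple[BeatDataset, BeatDataset]:
    """Segment + encode all records into raw DS1 and DS2 datasets."""
    images = {"DS1": [], "DS2": []}
    for rec in records:
        part = partitions[rec.record_id]
        beats = segment_beats(rec)
        images[part].extend(encoder.transform(beats))
    return (BeatDataset.from_images(images["DS1"], "DS1"),
            BeatDataset.from_images(images["DS2"], "DS2"))


def counts_table(ds1: BeatDataset, ds2: BeatDataset,
                 plan: AugmentationPlan | None = None) -> dict:
    """Per-class bookkeeping: pre/post balancing and per-partition counts."""
    plan = plan or AugmentationPlan()
    c1, c2 = ds1.class_counts(), ds2.class_counts()
    pre = {c: c1[c] + c2[c] for c in c1}
    post_ds1 = plan.projected_counts(c1)
    post = {c: post_ds1[c] + c2[c] for c in c1}
    return {
        "before": {"counts": pre, "total": sum(pre.values()),
                   "percent": class_shares(pre)},
        "after": {"counts": post, "total": sum(post.values()),
                  "percent": class_shares(post)},
        "DS1": {"counts": post_ds1, "total": sum(post_ds1.values())},
        "DS2": {"counts": c2, "total": sum(c2.values())},
    }


def run_end_to_end(data_dir: str | Path, config: RunConfig,
                   log: callable = None) -> dict:
    """Preprocess, balance, train and evaluate; returns a result bundle."""
    encoder = CWTScalogram(wavelet=config.wavelet, n_scales=config.n_scales,
                           fmin=config.fmin, fmax=config.fmax,
                           image_size=config.image_size,
                           channel_mode=config.channel_mode)
    records, partitions = load_records(data_dir)
    ds1_raw, ds2 = build_datasets(records, partitions, encoder)
    plan = AugmentationPlan(factors=dict(config.factors))
    ds1 = balance_dataset(ds1_raw, plan)
    clf = RACNNClassifier(
        input_size=config.image_size, stem_channels=config.stem_channels,
        groups=config.groups, epochs=config.epochs,
        batch_size=config.batch_size, initial_lr=config.initial_lr,
        lr_step_epochs=config.lr_step_epochs, lr_gamma=config.lr_gamma,
        seed=config.seed, use_rblock=config.use_rblock,
        use_ablock=config.use_ablock, channel_att=config.channel_att,
        spatial_att=config.spatial_att, top_skip=config.top_skip,
        middle_layer=config.middle_layer)
    clf.fit(ds1.images, ds1.labels, log=log)
    train_acc = float(np.mean(clf.predict(ds1.images) == ds1.labels))
    report = EvalReport(confusion=confusion_matrix(ds2.labels, clf.predict(ds2.images)))
    return {"classifier": clf, "report": report,
            "train_accuracy": 100.0 * train_acc,
            "counts": counts_table(ds1_raw, ds2, plan),
            "ds1_raw": ds1_raw, "ds1": ds1, "ds2": ds2}
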
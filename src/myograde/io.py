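"""Data model and file I/O for 4-channel muscle recordings and segment sets.

A :class:`Recording` is one subject/session of synchronized surface-EMG and
piezoelectric strain signals sampled at 1 kHz.  Two on-disk dialects exist:

* a human-readable comma-delimited text file with a ``time_index`` column,
  one column per channel and ``#``-prefixed metadata lines, and
* an ``.npz`` container for windowed segment tensors.

Channel order is canonicalized to ``(semg_1, piezo_1, semg_2, piezo_2)``
everywhere; time is kept in 0-based sample indices.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

CHANNEL_NAMES = ("semg_1", "piezo_1", "semg_2", "piezo_2")
SAMPLING_RATE = 1000
SEGMENT_LEN = 200

MUSCLES = ("TA", "EHL")


class FormatError(ValueError):
    """Raised when a file does not match the expected dialect."""


class ValidationError(ValueError):
    """Raised when data violates a Recording/SegmentSet invariant."""


@dataclass
class Recording:
    """One 4-channel recording at 1 kHz with optional clinician grade.

    ``channels`` has shape (4, n_samples) in canonical channel order.
    ``meta`` carries free-form generation metadata (e.g. the activity
    interval planted by the synthetic generator) and survives text round
    trips.
    """

    subject_id: str
    channels: np.ndarray
    muscle: str = "TA"
    sampling_rate: int = SAMPLING_RATE
    coarse_grade: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.channels.ndim != 2 or self.channels.shape[0] != 4:
            raise ValidationError(
                f"expected 4 equal-length channels, got array of shape "
                f"{self.channels.shape}")
        if self.n_samples < SEGMENT_LEN:
            raise ValidationError(
                f"channels must hold at least {SEGMENT_LEN} samples, "
                f"got {self.n_samples}")
        if self.sampling_rate != SAMPLING_RATE:
            raise ValidationError(
                f"sampling_rate must be {SAMPLING_RATE} samples/s "
                f"(got {self.sampling_rate}); the windowing constants assume it")
        if self.muscle not in MUSCLES:
            raise ValidationError(f"muscle must be one of {MUSCLES}")
        if self.coarse_grade is not None and self.coarse_grade not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"coarse_grade must be in 1..5, got {self.coarse_grade}")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        return self.channels[CHANNEL_NAMES.index(name)]

    def with_channels(self, channels: np.ndarray) -> "Recording":
        return replace(self, channels=np.asarray(channels, dtype=np.float64))


@dataclass
class SegmentSet:
    """Windowed segments of shape (n_segments, 4, 200) with provenance.

    ``labels`` are per-segment integer class labels (coarse grade 1..5 or a
    fine 25-class index), or ``None`` for unlabeled data.  ``subject_ids``
    and ``starts`` record which recording and window start produced each
    segment.  ``bounds`` maps subject_id -> (4, 2) array of per-channel
    (min, max) used for normalization, stored so unseen data can be mapped
    with the same bounds.
    """

    data: np.ndarray
    labels: np.ndarray | None = None
    subject_ids: np.ndarray | None = None
    starts: np.ndarray | None = None
    bounds: dict[str, np.ndarray] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[1] != 4:
            raise ValidationError(
                f"segment data must have shape (n, 4, win), got {self.data.shape}")
        n = len(self.data)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValidationError("labels length mismatch")
        if self.subject_ids is not None:
            self.subject_ids = np.asarray(self.subject_ids, dtype=object)
            if len(self.subject_ids) != n:
                raise ValidationError("subject_ids length mismatch")
        if self.starts is not None:
            self.starts = np.asarray(self.starts, dtype=np.int64)
            if len(self.starts) != n:
                raise ValidationError("starts length mismatch")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_segments(self) -> int:
        return len(self.data)

    def subset(self, idx) -> "SegmentSet":
        idx = np.asarray(idx)
        if idx.dtype != bool:
            idx = idx.astype(np.int64)
        return SegmentSet(
            data=self.data[idx],
            labels=None if self.labels is None else self.labels[idx],
            subject_ids=None if self.subject_ids is None else self.subject_ids[idx],
            starts=None if self.starts is None else self.starts[idx],
            bounds=dict(self.bounds),
            normalized=self.normalized,
        )


def _canonical_order(columns: list[str]) -> list[int]:
    missing = [c for c in CHANNEL_NAMES if c not in columns]
    if missing:
        raise FormatError(f"missing channel column(s): {missing}")
    return [columns.index(c) for c in CHANNEL_NAMES]


def read_recording(path, format: str = "text") -> Recording:
    """Read a Recording from the text dialect (or npz container)."""
    path = Path(path)
    if format == "npz":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta_json"]))
            return Recording(
                subject_id=meta["subject"],
                channels=z["channels"],
                muscle=meta.get("muscle", "TA"),
                sampling_rate=int(meta.get("fs", SAMPLING_RATE)),
                coarse_grade=meta.get("grade"),
                meta=meta.get("meta", {}),
            )
    if format != "text":
        raise FormatError(f"unknown format {format!r}")
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    cols = list(df.columns)
    if "time_index" in cols:
        cols.remove("time_index")
    if len(cols) != 4:
        raise FormatError(
            f"expected 4 channel columns {CHANNEL_NAMES}, found {cols}")
    order = _canonical_order(cols)
    channels = df[cols].to_numpy(dtype=np.float64).T[order]
    fs = int(meta.get("fs", SAMPLING_RATE))
    grade = meta.get("grade")
    extra = json.loads(meta["meta"]) if "meta" in meta else {}
    return Recording(
        subject_id=meta.get("subject", path.stem),
        channels=channels,
        muscle=meta.get("muscle", "TA"),
        sampling_rate=fs,
        coarse_grade=None if grade in (None, "", "None") else int(grade),
        meta=extra,
    )


def write_recording(rec: Recording, path, format: str = "text") -> None:
    """Write a Recording; ``read_recording`` reproduces it bit-exactly.

    The text dialect prints full float precision (repr round trip).
    """
    rec.validate()
    path = Path(path)
    if format == "npz":
        meta = {"subject": rec.subject_id, "muscle": rec.muscle,
                "fs": rec.sampling_rate, "grade": rec.coarse_grade,
                "meta": rec.meta}
        np.savez(path, channels=rec.channels, meta_json=json.dumps(meta))
        return
    if format != "text":
        raise FormatError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        fh.write(f"# subject={rec.subject_id}\n")
        fh.write(f"# muscle={rec.muscle}\n")
        fh.write(f"# fs={rec.sampling_rate}\n")
        if rec.coarse_grade is not None:
            fh.write(f"# grade={rec.coarse_grade}\n")
        if rec.meta:
            fh.write(f"# meta={json.dumps(rec.meta)}\n")
        fh.write("time_index," + ",".join(CHANNEL_NAMES) + "\n")
        for i in range(rec.n_samples):
            row = ",".join(repr(float(v)) for v in rec.channels[:, i])
            fh.write(f"{i},{row}\n")


def save_segments(segs: SegmentSet, path) -> None:
    """Lossless npz round trip including labels, provenance and bounds."""
    path = Path(path)
    payload = {"data": segs.data}
    meta = {"normalized": segs.normalized,
            "has_labels": segs.labels is not None,
            "has_provenance": segs.subject_ids is not None,
            "bound_subjects": sorted(segs.bounds)}
    if segs.labels is not None:
        payload["labels"] = segs.labels.astype(np.int64)
    if segs.subject_ids is not None:
        payload["subject_ids"] = np.array([str(s) for s in segs.subject_ids])
        payload["starts"] = segs.starts
    for i, subj in enumerate(meta["bound_subjects"]):
        payload[f"bounds_{i}"] = segs.bounds[subj]
    payload["meta_json"] = json.dumps(meta)
    np.savez(path, **payload)


def load_segments(path) -> SegmentSet:
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta_json"]))
            data = z["data"]
            if data.ndim != 3 or data.shape[1] != 4:
                raise FormatError(f"bad segment tensor shape {data.shape}")
            bounds = {subj: z[f"bounds_{i}"]
                      for i, subj in enumerate(meta["bound_subjects"])}
            return SegmentSet(
                data=data,
                labels=z["labels"] if meta["has_labels"] else None,
                subject_ids=z["subject_ids"].astype(object)
                if meta["has_provenance"] else None,
                starts=z["starts"] if meta["has_provenance"] else None,
                bounds=bounds,
                normalized=meta["normalized"],
            )
    except (KeyError, OSError, ValueError, zipfile.BadZipFile) as exc:
        if isinstance(exc, (FormatError, ValidationError)):
            raise
        raise FormatError(f"cannot read segment container {path}: {exc}") from exc
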
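"""Domain types and I/O for PPG segments, artifact annotations, and attention maps.

Conventions used throughout the package:

* sample indices are 0-based and every index range is half-open ``[start, end)``;
* annotation files carry times in seconds, converted to sample indices via
  ``floor(t * fs)``;
* a 30-second segment sampled at 240 Hz has ``240 * 30 + 1 = 7201`` samples
  (inclusive final endpoint) — the default geometry of the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_FS = 240.0
DEFAULT_DURATION_S = 30.0

__all__ = [
    "DEFAULT_FS",
    "DEFAULT_DURATION_S",
    "QualityLabel",
    "ValidationError",
    "FormatError",
    "PpgSegment",
    "AnnotationIntervals",
    "LabeledDataset",
    "n_samples_for",
    "intervals_to_mask",
    "mask_to_sections",
    "sections_to_mask",
    "read_dataset",
    "write_dataset",
    "read_attention_maps",
    "write_attention_maps",
]


class ValidationError(ValueError):
    """An object violates a domain invariant (e.g. overlapping intervals)."""


class FormatError(ValueError):
    """An input file is malformed or inconsistent with the dataset."""


class QualityLabel(IntEnum):
    """Segment quality label. ``ARTIFACT_FREE`` is the positive class."""

    ARTIFACTUAL = 0
    ARTIFACT_FREE = 1
    UNLABELED = -1


def n_samples_for(fs: float, duration_s: float) -> int:
    """Number of samples in a segment of ``duration_s`` seconds at ``fs`` Hz,
    counting an inclusive final endpoint (30 s at 240 Hz -> 7201)."""
    return int(round(fs * duration_s)) + 1


@dataclass
class PpgSegment:
    """A fixed-length 1D PPG segment.

    Parameters
    ----------
    record_id : str
        Unique identifier of the segment.
    samples : ndarray of shape (n,)
        The waveform. Must be finite, with ``n >= 2``.
    fs : float
        Sampling rate in Hz.
    label : QualityLabel
        Quality class; ``UNLABELED`` if unknown.
    """

    record_id: str
    samples: np.ndarray
    fs: float = DEFAULT_FS
    label: QualityLabel = QualityLabel.UNLABELED

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValidationError("segment must be a 1D vector with n >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("segment contains non-finite samples")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        self.label = QualityLabel(self.label)

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        """Segment duration assuming an inclusive final endpoint."""
        return (self.n - 1) / self.fs


@dataclass
class AnnotationIntervals:
    """Expert artifact annotations as (onset_s, offset_s) pairs in seconds.

    Intervals must be sorted by onset, pairwise non-overlapping, and lie
    within ``[0, duration_s]``.
    """

    record_id: str
    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = [(float(a), float(b)) for a, b in self.intervals]
        prev_end = None
        for onset, offset in self.intervals:
            if not onset < offset:
                raise ValidationError(
                    f"{self.record_id}: interval onset {onset} must precede offset {offset}"
                )
            if onset < 0:
                raise ValidationError(f"{self.record_id}: negative onset {onset}")
            if prev_end is not None and onset < prev_end:
                raise ValidationError(
                    f"{self.record_id}: intervals overlap or are unsorted at onset {onset}"
                )
            prev_end = offset

    def validate_duration(self, duration_s: float) -> None:
        if self.intervals and self.intervals[-1][1] > duration_s + 1e-9:
            raise ValidationError(
                f"{self.record_id}: interval extends past segment end "
                f"({self.intervals[-1][1]} > {duration_s} s)"
            )

    @property
    def total_s(self) -> float:
        return float(sum(b - a for a, b in self.intervals))


def _time_to_index(t: float, fs: float) -> int:
    # floor(t * fs), guarded against float representation of exact products
    return int(math.floor(t * fs + 1e-9))


def intervals_to_mask(intervals: AnnotationIntervals, fs: float, n: int) -> np.ndarray:
    """Rasterize second-based annotation intervals to a binary per-sample mask.

    Sample ``j`` is 1 iff ``floor(onset * fs) <= j < floor(offset * fs)`` for
    some interval (half-open, 0-based).

    Returns
    -------
    ndarray of shape (n,), dtype int8, values in {0, 1}
    """
    duration_s = (n - 1) / fs
    intervals.validate_duration(duration_s)
    mask = np.zeros(n, dtype=np.int8)
    for onset, offset in intervals.intervals:
        start = _time_to_index(onset, fs)
        stop = min(_time_to_index(offset, fs), n)
        mask[start:stop] = 1
    return mask


def mask_to_sections(mask: np.ndarray) -> list[tuple[int, int, int]]:
    """Decompose a binary mask into maximal constant-value runs ("sections").

    Returns an ordered list of ``(start_idx, end_idx, value)`` half-open runs
    that tile ``[0, n)`` with alternating values.
    """
    mask = _check_mask(mask)
    boundaries = np.flatnonzero(np.diff(mask)) + 1
    edges = np.concatenate(([0], boundaries, [mask.size]))
    return [
        (int(a), int(b), int(mask[a])) for a, b in zip(edges[:-1], edges[1:])
    ]


def sections_to_mask(sections: Sequence[tuple[int, int, int]], n: int) -> np.ndarray:
    """Inverse of :func:`mask_to_sections`."""
    mask = np.zeros(n, dtype=np.int8)
    for start, end, value in sections:
        mask[start:end] = value
    return mask


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 1:
        raise ValidationError("annotation mask must be 1D")
    if not np.isin(mask, (0, 1)).all():
        raise ValidationError("annotation mask must be strictly binary")
    return mask.astype(np.int8, copy=False)


@dataclass
class LabeledDataset:
    """A collection of equally-sized segments with optional annotation masks.

    ``masks[i]`` is either a binary vector aligned with ``segments[i]`` or
    ``None`` for unannotated records. Explainability metrics consume only the
    annotated (artifactual) records; classification consumes all of them.
    """

    segments: list[PpgSegment]
    masks: list[np.ndarray | None]

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.masks):
            raise ValidationError("segments and masks differ in length")
        if self.segments:
            n0, fs0 = self.segments[0].n, self.segments[0].fs
            for seg in self.segments:
                if seg.n != n0 or seg.fs != fs0:
                    raise ValidationError("all segments must share n and fs")
            for seg, mask in zip(self.segments, self.masks):
                if mask is not None and _check_mask(mask).size != n0:
                    raise ValidationError(
                        f"{seg.record_id}: mask length differs from segment length"
                    )

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n(self) -> int:
        return self.segments[0].n

    @property
    def fs(self) -> float:
        return self.segments[0].fs

    @property
    def X(self) -> np.ndarray:
        """Signal matrix of shape (n_records, n)."""
        return np.stack([seg.samples for seg in self.segments])

    @property
    def y(self) -> np.ndarray:
        """Integer label vector (0 artifactual, 1 artifact-free, -1 unlabeled)."""
        return np.array([int(seg.label) for seg in self.segments])

    @property
    def record_ids(self) -> list[str]:
        return [seg.record_id for seg in self.segments]

    def annotated(self) -> "LabeledDataset":
        """Subset of records that carry an annotation mask."""
        keep = [i for i, m in enumerate(self.masks) if m is not None]
        return LabeledDataset(
            [self.segments[i] for i in keep], [self.masks[i] for i in keep]
        )

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        idx = list(indices)
        return LabeledDataset(
            [self.segments[i] for i in idx], [self.masks[i] for i in idx]
        )


# ---------------------------------------------------------------------------
# File I/O
#
# Signals: wide CSV (record_id[, label], s0..s{n-1}) or an HDF5 container with
#   /signals (records x n), /record_id, and an "fs" attribute.
# Annotations: CSV with header record_id,onset_s,offset_s — a BED-like
#   half-open interval table in seconds.
# Attention maps: same wide conventions, tagged with the saliency method name.
# ---------------------------------------------------------------------------


def write_dataset(
    dataset: LabeledDataset,
    signals_path: str | Path,
    annotations_path: str | Path,
    intervals: Sequence[AnnotationIntervals] | None = None,
) -> None:
    """Write a dataset as a wide signals CSV/HDF5 plus an interval-table CSV.

    If ``intervals`` is not given, intervals are reconstructed from the stored
    masks (each mask run becomes one interval)."""
    signals_path = Path(signals_path)
    fs = dataset.fs
    if signals_path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(signals_path, "w") as f:
            f.create_dataset("signals", data=dataset.X)
            f.create_dataset(
                "record_id", data=np.array(dataset.record_ids, dtype="S")
            )
            f.create_dataset("label", data=dataset.y)
            f.attrs["fs"] = fs
    else:
        frame = pd.DataFrame(dataset.X, columns=[f"s{j}" for j in range(dataset.n)])
        frame.insert(0, "record_id", dataset.record_ids)
        frame.insert(1, "label", dataset.y)
        frame.to_csv(signals_path, index=False)

    rows = []
    if intervals is not None:
        for iv in intervals:
            rows.extend(
                {"record_id": iv.record_id, "onset_s": a, "offset_s": b}
                for a, b in iv.intervals
            )
    else:
        for seg, mask in zip(dataset.segments, dataset.masks):
            if mask is None:
                continue
            for start, end, value in mask_to_sections(mask):
                if value == 1:
                    rows.append(
                        {
                            "record_id": seg.record_id,
                            "onset_s": start / fs,
                            "offset_s": end / fs,
                        }
                    )
    pd.DataFrame(rows, columns=["record_id", "onset_s", "offset_s"]).to_csv(
        annotations_path, index=False
    )


def _read_signals(signals_path: Path, fs: float | None):
    if signals_path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(signals_path, "r") as f:
            X = np.asarray(f["signals"])
            ids = [s.decode() for s in f["record_id"][()]]
            labels = (
                np.asarray(f["label"]) if "label" in f else np.full(len(ids), -1)
            )
            fs = float(f.attrs["fs"]) if fs is None else fs
        return X, ids, labels, fs

    frame = pd.read_csv(signals_path)
    if "record_id" not in frame.columns:
        raise FormatError("signals CSV must have a record_id column")
    ids = frame["record_id"].astype(str).tolist()
    if "label" in frame.columns:
        labels = frame["label"].to_numpy()
        X = frame.drop(columns=["record_id", "label"]).to_numpy(dtype=float)
    else:
        labels = np.full(len(ids), -1)
        X = frame.drop(columns=["record_id"]).to_numpy(dtype=float)
    if fs is None:
        raise FormatError("fs must be given when reading signals from CSV")
    return X, ids, labels, fs


def read_dataset(
    signals_path: str | Path,
    annotations_path: str | Path | None = None,
    fs: float | None = None,
) -> LabeledDataset:
    """Load a dataset, materializing annotation masks from the interval table.

    Records listed in the annotation table but absent from the signals file
    raise :class:`FormatError`. Records without a stored label are labeled
    ``ARTIFACTUAL`` when annotated and ``UNLABELED`` otherwise.
    """
    X, ids, labels, fs = _read_signals(Path(signals_path), fs)
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate record_id in signals file")
    n = X.shape[1]

    by_record: dict[str, list[tuple[float, float]]] = {}
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path)
        expected = {"record_id", "onset_s", "offset_s"}
        if not expected.issubset(ann.columns):
            raise FormatError(f"annotation table must have columns {sorted(expected)}")
        known = set(ids)
        for rid, group in ann.groupby("record_id", sort=False):
            rid = str(rid)
            if rid not in known:
                raise FormatError(f"annotation references unknown record_id {rid!r}")
            by_record[rid] = list(zip(group["onset_s"], group["offset_s"]))

    segments, masks = [], []
    for rid, row, raw_label in zip(ids, X, labels):
        pairs = by_record.get(rid)
        if pairs is not None:
            mask = intervals_to_mask(AnnotationIntervals(rid, pairs), fs, n)
            label = QualityLabel(int(raw_label)) if raw_label != -1 else QualityLabel.ARTIFACTUAL
        else:
            mask = None
            label = QualityLabel(int(raw_label))
        segments.append(PpgSegment(rid, row, fs=fs, label=label))
        masks.append(mask)
    return LabeledDataset(segments, masks)


def write_attention_maps(
    path: str | Path,
    record_ids: Sequence[str],
    maps: np.ndarray,
    method: str,
) -> None:
    """Write per-record attention vectors with the saliency method recorded."""
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "w") as f:
            dset = f.create_dataset("attention", data=maps)
            dset.attrs["method"] = method
            f.create_dataset("record_id", data=np.array(list(record_ids), dtype="S"))
    else:
        frame = pd.DataFrame(maps, columns=[f"s{j}" for j in range(maps.shape[1])])
        frame.insert(0, "record_id", list(record_ids))
        frame.insert(1, "method", method)
        frame.to_csv(path, index=False)


def read_attention_maps(path: str | Path) -> tuple[list[str], np.ndarray, str]:
    """Read attention maps written by :func:`write_attention_maps`.

    Returns ``(record_ids, maps, method)``."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "r") as f:
            maps = np.asarray(f["attention"])
            method = str(f["attention"].attrs["method"])
            ids = [s.decode() for s in f["record_id"][()]]
        return ids, maps, method
    frame = pd.read_csv(path)
    ids = frame["record_id"].astype(str).tolist()
    method = str(frame["method"].iloc[0]) if len(frame) else ""
    maps = frame.drop(columns=["record_id", "method"]).to_numpy(dtype=float)
    return ids, maps, method
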
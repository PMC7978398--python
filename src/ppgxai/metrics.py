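"""Explainability metrics: Congruence and Annotation Classification.

Both metrics compare a model's nonnegative attention map ``z_hat`` with a
binary expert annotation mask ``z`` over a test set of artifactual segments.

*Congruence* is the proportion of total attention mass lying inside the
annotated region of one segment,

    Cong(z, z_hat) = sum_j z_j * z_hat_j / sum_j z_hat_j,

averaged unweighted over the records of a dataset. It measures whether the
attention is in a valid place but says nothing about its coverage.

*Annotation Classification* measures coverage: attention scores are used to
"classify" whether units of the signal are annotated, and the AUROC of that
classification is the metric. The three variants differ only in the unit:

* pixel — every sample is a unit, scored by its own attention;
* sectional — each maximal constant-annotation run is a unit, scored by the
  maximum attention inside it;
* interval — fixed-duration tiles (default 5 s) are units, scored by their
  maximum attention and labeled positive if they overlap any annotation.

Units are pooled across the whole dataset into a single ROC by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn import metrics as _skm

from .core import mask_to_sections

__all__ = [
    "UndefinedCongruenceError",
    "DegenerateAurocError",
    "ScoredUnits",
    "RocCurve",
    "congruence",
    "congruence_dataset",
    "auroc",
    "roc_curve",
    "pixel_units",
    "sectional_units",
    "interval_units",
    "annotation_classification",
    "section_length_summary",
    "VARIANTS",
]

logger = logging.getLogger("ppgxai")

VARIANTS = ("pixel", "sectional", "interval")

AttentionMaskPairs = Sequence[tuple[np.ndarray, np.ndarray]]


class UndefinedCongruenceError(ValueError):
    """Congruence is undefined because the attention map has zero total mass."""


class DegenerateAurocError(ValueError):
    """AUROC is undefined because only one class of units is present."""


@dataclass
class ScoredUnits:
    """Paired (score, binary label) units feeding one pooled ROC."""

    scores: np.ndarray
    labels: np.ndarray
    unit_kind: str = "pixel"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        self.labels = np.asarray(self.labels).ravel().astype(int)
        if self.scores.size != self.labels.size:
            raise ValueError("scores and labels must have equal length")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return self.scores.size


@dataclass
class RocCurve:
    """A threshold-sweep ROC curve: starts at (0,0), ends at (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float = field(default=math.nan)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


def _check_pair(attention: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    attention = np.asarray(attention, dtype=float).ravel()
    mask = np.asarray(mask).ravel()
    if attention.size != mask.size:
        raise ValueError("attention map and annotation mask differ in length")
    if np.any(attention < 0):
        raise ValueError("attention map must be nonnegative")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("annotation mask must be binary")
    return attention, mask.astype(int)


def congruence(attention: np.ndarray, mask: np.ndarray) -> float:
    """Proportion of attention mass inside the annotated region of one record.

    Raises
    ------
    UndefinedCongruenceError
        If the attention map sums to zero (the denominator vanishes).
    """
    attention, mask = _check_pair(attention, mask)
    total = attention.sum()
    if total <= 0:
        raise UndefinedCongruenceError("attention map has zero total mass")
    return float((attention * mask).sum() / total)


def congruence_dataset(pairs: AttentionMaskPairs) -> float:
    """Unweighted mean of per-record congruences over a dataset.

    Records with all-zero attention are skipped with a logged warning; if
    every record is undefined, :class:`UndefinedCongruenceError` is raised.
    """
    values = []
    skipped = 0
    for attention, mask in pairs:
        try:
            values.append(congruence(attention, mask))
        except UndefinedCongruenceError:
            skipped += 1
    if skipped:
        logger.warning("congruence undefined on %d record(s); skipped", skipped)
    if not values:
        raise UndefinedCongruenceError("congruence undefined on every record")
    return float(np.mean(values))


def auroc(units: ScoredUnits) -> float:
    """Area under the attention-threshold ROC, as the Mann-Whitney statistic.

    Equals the fraction of (positive, negative) unit pairs where the
    positive unit scores higher, counting ties as 1/2. Computed with the
    tie-corrected rank formula, which matches brute-force pair counting
    exactly.
    """
    labels, scores = units.labels, units.scores
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateAurocError(
            f"both unit classes required (got {n_pos} positive, {n_neg} negative)"
        )
    ranks = rankdata(scores)  # average ranks: ties get half credit
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(units: ScoredUnits) -> RocCurve:
    """Full ROC from the sorted-threshold sweep (tied scores move jointly).

    The ``auroc`` field is the trapezoidal area under the curve and agrees
    with :func:`auroc` to floating-point precision.
    """
    labels = units.labels
    if labels.sum() in (0, labels.size):
        raise DegenerateAurocError("both unit classes required for a ROC curve")
    fpr, tpr, thresholds = _skm.roc_curve(labels, units.scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auroc=float(_skm.auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# Unit constructions for the three Annotation Classification variants
# ---------------------------------------------------------------------------


def pixel_units(pairs: AttentionMaskPairs) -> ScoredUnits:
    """One unit per sample, pooled across records: score ``z_hat_ij``,
    label ``z_ij``."""
    scores, labels = [], []
    for attention, mask in pairs:
        attention, mask = _check_pair(attention, mask)
        scores.append(attention)
        labels.append(mask)
    return ScoredUnits(np.concatenate(scores), np.concatenate(labels), "pixel")


def sectional_units(pairs: AttentionMaskPairs) -> ScoredUnits:
    """One unit per annotation-delimited section: score = max attention in
    the section, label = the section's annotation value."""
    scores, labels = [], []
    for attention, mask in pairs:
        attention, mask = _check_pair(attention, mask)
        for start, end, value in mask_to_sections(mask):
            scores.append(attention[start:end].max())
            labels.append(value)
    return ScoredUnits(np.array(scores), np.array(labels), "section")


def _interval_edges(n: int, fs: float, interval_len_s: float) -> np.ndarray:
    """Tile ``n`` samples into fixed intervals of ``interval_len_s`` seconds.

    The tiling covers the segment's duration ``(n - 1)/fs``; the final
    interval absorbs the inclusive endpoint sample, so a 30-s segment at
    240 Hz (7201 samples) yields exactly six 5-s intervals. A remainder
    shorter than the interval length is kept as its own interval.
    """
    if interval_len_s <= 0:
        raise ValueError("interval length must be positive")
    duration_s = (n - 1) / fs
    samples_per = int(round(interval_len_s * fs))
    if samples_per >= n:
        logger.warning(
            "interval length %.3g s >= record duration %.3g s; using one whole-record interval",
            interval_len_s,
            duration_s,
        )
        return np.array([0, n])
    n_intervals = math.ceil((n - 1) / samples_per)
    edges = np.arange(n_intervals + 1) * samples_per
    edges[-1] = n
    return edges


def interval_units(
    pairs: AttentionMaskPairs, fs: float, interval_len_s: float = 5.0
) -> ScoredUnits:
    """One unit per fixed-duration tile: score = max attention in the tile,
    label = 1 iff any annotated sample overlaps it (any-overlap rule)."""
    scores, labels = [], []
    for attention, mask in pairs:
        attention, mask = _check_pair(attention, mask)
        edges = _interval_edges(attention.size, fs, interval_len_s)
        for a, b in zip(edges[:-1], edges[1:]):
            scores.append(attention[a:b].max())
            labels.append(int(mask[a:b].any()))
    return ScoredUnits(np.array(scores), np.array(labels), "interval")


def annotation_classification(
    pairs: AttentionMaskPairs,
    variant: str = "pixel",
    fs: float | None = None,
    interval_len_s: float = 5.0,
) -> float:
    """Annotation Classification AUROC for one variant over pooled units."""
    if variant == "pixel":
        units = pixel_units(pairs)
    elif variant == "sectional":
        units = sectional_units(pairs)
    elif variant == "interval":
        if fs is None:
            raise ValueError("interval variant requires the sampling rate fs")
        units = interval_units(pairs, fs, interval_len_s)
    else:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    return auroc(units)


def section_length_summary(pairs: AttentionMaskPairs) -> dict:
    """Mean section length (in samples) per annotation class.

    Sectional AUROC scores each section by its maximum attention, which
    biases longer sections toward higher scores; annotated sections are
    typically much shorter than unannotated ones, so this summary should be
    read alongside any Sectional result.
    """
    lengths: dict[int, list[int]] = {0: [], 1: []}
    for _, mask in pairs:
        for start, end, value in mask_to_sections(np.asarray(mask)):
            lengths[value].append(end - start)
    return {
        "mean_len_unannotated": float(np.mean(lengths[0])) if lengths[0] else math.nan,
        "mean_len_annotated": float(np.mean(lengths[1])) if lengths[1] else math.nan,
        "n_unannotated": len(lengths[0]),
        "n_annotated": len(lengths[1]),
    }
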
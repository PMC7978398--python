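"""Synthetic PPG segments, artifact annotations, and attention maps.

Everything the metrics and the study drivers consume can be generated here
with known ground truth: quasi-periodic pulse waveforms, injected artifact
episodes whose onsets/offsets are returned exactly, and attention maps with
a controllable fraction of mass inside the annotated region (so the
expected Congruence is known by construction).

The waveform is a two-Gaussian beat template — a systolic peak plus a
smaller, delayed dicrotic bump — with per-beat period jitter, slow baseline
wander, and low-amplitude sensor noise. It is morphologically plausible but
makes no hemodynamic claims; the metrics under test are waveform-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import (
    AnnotationIntervals,
    LabeledDataset,
    PpgSegment,
    QualityLabel,
    intervals_to_mask,
    mask_to_sections,
)

__all__ = [
    "ArtifactKind",
    "ArtifactSpec",
    "AttentionProfile",
    "SyntheticAttentionSpec",
    "PlacementError",
    "simulate_clean_ppg",
    "inject_artifacts",
    "synthetic_attention",
    "make_labeled_dataset",
]


class PlacementError(RuntimeError):
    """Could not place the requested number of non-overlapping episodes."""


class ArtifactKind(str, Enum):
    GAUSSIAN_NOISE = "gaussian_noise"
    FLATLINE = "flatline"
    SPIKE_BURST = "spike_burst"
    SATURATION = "saturation"


class AttentionProfile(str, Enum):
    UNIFORM = "uniform"
    RANDOM_UNIFORM = "random_uniform"
    PEAKED = "peaked"


@dataclass
class ArtifactSpec:
    """Artifact-episode generator settings.

    ``amplitude`` is relative to the clean signal's standard deviation; the
    default (4x) makes episodes visually and statistically obvious, so a
    small CNN separates the classes within minutes of CPU training.
    """

    kind: ArtifactKind = ArtifactKind.GAUSSIAN_NOISE
    duration_range_s: tuple[float, float] = (2.0, 8.0)
    amplitude: float = 4.0
    count: int = 2

    def __post_init__(self) -> None:
        self.kind = ArtifactKind(self.kind)
        lo, hi = self.duration_range_s
        if not 0 < lo <= hi:
            raise ValueError("duration range must satisfy 0 < min <= max")
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass
class SyntheticAttentionSpec:
    """Target congruence and spatial profile for a synthetic attention map."""

    target_congruence: float = 0.5
    profile: AttentionProfile = AttentionProfile.UNIFORM
    seed: int = 0

    def __post_init__(self) -> None:
        self.profile = AttentionProfile(self.profile)
        if not 0.0 <= self.target_congruence <= 1.0:
            raise ValueError("target congruence must lie in [0, 1]")


def simulate_clean_ppg(
    duration_s: float = 30.0,
    fs: float = 240.0,
    heart_rate_bpm: float = 70.0,
    jitter: float = 0.02,
    seed: int = 0,
    baseline_wander: float = 0.05,
    noise: float = 0.01,
    record_id: str = "synthetic",
) -> PpgSegment:
    """Quasi-periodic artifact-free PPG segment of ``fs * duration + 1`` samples.

    Each beat is a systolic Gaussian bump plus a smaller delayed dicrotic
    bump. ``jitter`` is the fractional standard deviation of the beat
    period; ``baseline_wander`` and ``noise`` are amplitudes relative to the
    unit-height systolic peak. Deterministic given ``seed``.
    """
    if not 30.0 <= heart_rate_bpm <= 220.0:
        raise ValueError(f"non-physiologic heart rate {heart_rate_bpm} bpm")
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration_s)) + 1
    t = np.arange(n) / fs
    period = 60.0 / heart_rate_bpm

    x = np.zeros(n)
    beat_start = 0.0
    while beat_start < duration_s + period:
        # systolic peak at 30% of the beat, dicrotic bump at 65%
        x += np.exp(-0.5 * ((t - beat_start - 0.30 * period) / (0.10 * period)) ** 2)
        x += 0.35 * np.exp(
            -0.5 * ((t - beat_start - 0.65 * period) / (0.12 * period)) ** 2
        )
        beat_start += period * (1.0 + jitter * rng.standard_normal())

    if baseline_wander > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += baseline_wander * np.sin(2 * np.pi * 0.2 * t + phase)
    if noise > 0:
        x += noise * rng.standard_normal(n)
    return PpgSegment(record_id, x, fs=fs, label=QualityLabel.ARTIFACT_FREE)


def _place_episodes(rng, n, fs, spec) -> list[tuple[int, int]]:
    """Non-overlapping [start, stop) sample ranges for ``spec.count`` episodes."""
    lo, hi = spec.duration_range_s
    placed: list[tuple[int, int]] = []
    for _ in range(spec.count):
        dur = int(round(rng.uniform(lo, hi) * fs))
        dur = min(max(dur, 1), n)
        ok = False
        for _try in range(1000):
            start = int(rng.integers(0, n - dur + 1))
            stop = start + dur
            if all(stop <= a or start >= b for a, b in placed):
                placed.append((start, stop))
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place {spec.count} non-overlapping episodes of "
                f"{lo}-{hi} s in a {(n - 1) / fs:.1f} s segment"
            )
    return sorted(placed)


def inject_artifacts(
    segment: PpgSegment, spec: ArtifactSpec, seed: int = 0
) -> tuple[PpgSegment, AnnotationIntervals]:
    """Corrupt a clean segment with annotated artifact episodes.

    The returned intervals exactly delimit the corrupted samples (half-open,
    on the sample grid); outside them the signal is bit-identical to the
    input. The returned segment is labeled ``ARTIFACTUAL`` when at least one
    episode was injected.
    """
    rng = np.random.default_rng(seed)
    x = segment.samples.copy()
    n, fs = segment.n, segment.fs
    sigma = float(np.std(x))
    episodes = _place_episodes(rng, n, fs, spec)

    for start, stop in episodes:
        sl = slice(start, stop)
        if spec.kind is ArtifactKind.GAUSSIAN_NOISE:
            x[sl] += spec.amplitude * sigma * rng.standard_normal(stop - start)
        elif spec.kind is ArtifactKind.FLATLINE:
            x[sl] = float(np.mean(x[sl]))
        elif spec.kind is ArtifactKind.SPIKE_BURST:
            k = max(1, (stop - start) // 10)
            pos = rng.choice(stop - start, size=k, replace=False)
            signs = rng.choice([-1.0, 1.0], size=k)
            x[start + pos] += signs * spec.amplitude * sigma * rng.uniform(0.5, 1.5, k)
        elif spec.kind is ArtifactKind.SATURATION:
            ceiling = float(np.quantile(segment.samples, 0.6))
            x[sl] = np.minimum(x[sl], ceiling)

    label = QualityLabel.ARTIFACTUAL if episodes else segment.label
    out = PpgSegment(segment.record_id, x, fs=fs, label=label)
    intervals = AnnotationIntervals(
        segment.record_id, [(start / fs, stop / fs) for start, stop in episodes]
    )
    return out, intervals


def synthetic_attention(
    mask: np.ndarray, spec: SyntheticAttentionSpec
) -> np.ndarray:
    """Attention map with total mass 1 and mass fraction exactly
    ``spec.target_congruence`` inside the annotated samples.

    The mass inside (and outside) the annotation is spread uniformly,
    with random per-sample weights, or peaked at the center of each run,
    according to ``spec.profile``; in every case the congruence of the
    result equals the target exactly (up to float rounding).
    """
    mask = np.asarray(mask).astype(int).ravel()
    p = spec.target_congruence
    inside = mask == 1
    n_in, n_out = int(inside.sum()), int((~inside).sum())
    if p > 0 and n_in == 0:
        raise ValueError("target congruence > 0 requires a non-empty annotated region")
    if p < 1 and n_out == 0:
        raise ValueError("target congruence < 1 requires a non-empty unannotated region")

    rng = np.random.default_rng(spec.seed)
    attention = np.zeros(mask.size, dtype=float)

    def region_weights(region: np.ndarray, count: int) -> np.ndarray:
        if spec.profile is AttentionProfile.UNIFORM:
            return np.ones(count)
        if spec.profile is AttentionProfile.RANDOM_UNIFORM:
            return rng.uniform(0.1, 1.0, count)
        # PEAKED: Gaussian bump centered in each constant run of the region
        w = np.zeros(mask.size)
        value = int(mask[np.flatnonzero(region)[0]])
        for start, end, run_value in mask_to_sections(mask):
            if run_value != value:
                continue
            center = (start + end - 1) / 2.0
            sigma = max((end - start) / 4.0, 0.5)
            j = np.arange(start, end)
            w[j] = np.exp(-0.5 * ((j - center) / sigma) ** 2)
        return w[region]

    if p > 0:
        w = region_weights(inside, n_in)
        attention[inside] = p * w / w.sum()
    if p < 1:
        w = region_weights(~inside, n_out)
        attention[~inside] = (1.0 - p) * w / w.sum()
    return attention


def make_labeled_dataset(
    n_clean: int,
    n_artifactual: int,
    spec: ArtifactSpec | None = None,
    seed: int = 0,
    duration_s: float = 30.0,
    fs: float = 240.0,
    heart_rate_range: tuple[float, float] = (55.0, 95.0),
) -> LabeledDataset:
    """Balanced-as-requested synthetic dataset with ground-truth masks.

    Clean records are labeled artifact-free with no mask; artifactual
    records carry the exact injected-episode mask. Deterministic given
    ``seed``.
    """
    if n_clean < 0 or n_artifactual < 0:
        raise ValueError("record counts must be >= 0")
    spec = spec or ArtifactSpec()
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration_s)) + 1
    segments, masks = [], []

    def one_clean(rid):
        return simulate_clean_ppg(
            duration_s=duration_s,
            fs=fs,
            heart_rate_bpm=rng.uniform(*heart_rate_range),
            seed=int(rng.integers(2**31 - 1)),
            record_id=rid,
        )

    for i in range(n_clean):
        segments.append(one_clean(f"clean_{i:04d}"))
        masks.append(None)
    for i in range(n_artifactual):
        clean = one_clean(f"art_{i:04d}")
        corrupted, intervals = inject_artifacts(
            clean, spec, seed=int(rng.integers(2**31 - 1))
        )
        segments.append(corrupted)
        masks.append(intervals_to_mask(intervals, fs, n))
    return LabeledDataset(segments, masks)
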
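"""Congruence, the AUROC engine, and the three annotation-unit constructions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgxai.metrics import (
    DegenerateAurocError,
    ScoredUnits,
    UndefinedCongruenceError,
    annotation_classification,
    auroc,
    congruence,
    congruence_dataset,
    interval_units,
    pixel_units,
    roc_curve,
    section_length_summary,
    sectional_units,
)


def pair_counting_auroc(scores, labels):
    """Brute-force Mann-Whitney oracle: fraction of (positive, negative)
    pairs with score_pos > score_neg, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    diff = pos[:, None] - neg[None, :]
    return ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size)


class TestCongruence:
    def test_all_ones_mask_gives_one(self, rng):
        att = rng.uniform(0.1, 1, 50)
        assert congruence(att, np.ones(50)) == 1.0

    def test_direct_arithmetic(self):
        assert congruence([1, 1, 2], [0, 1, 1]) == pytest.approx(0.75)

    def test_attention_outside_mask_gives_zero(self):
        assert congruence([1, 2, 0, 0], [0, 0, 1, 1]) == 0.0

    def test_uniform_attention_gives_mask_fraction(self, rng):
        mask = (rng.uniform(size=200) < 0.3).astype(int)
        assert congruence(np.full(200, 0.7), mask) == pytest.approx(
            mask.sum() / 200, abs=1e-12
        )

    @given(st.floats(1e-6, 1e6), st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_invariant_to_positive_rescaling(self, c, seed):
        r = np.random.default_rng(seed)
        att = r.uniform(0, 1, 30)
        mask = r.integers(0, 2, 30)
        if att.sum() == 0 or (c * att).sum() == 0:
            return
        v = congruence(att, mask)
        assert 0.0 <= v <= 1.0
        assert congruence(c * att, mask) == pytest.approx(v, abs=1e-9)

    def test_zero_attention_is_undefined(self):
        with pytest.raises(UndefinedCongruenceError):
            congruence(np.zeros(10), np.ones(10))

    def test_dataset_mean_and_skip(self, caplog):
        pairs = [
            (np.array([1.0, 0, 0, 0]), np.array([1, 0, 0, 0])),  # cong 1.0
            (np.array([1.0, 1, 1, 1]), np.array([1, 1, 0, 0])),  # cong 0.5
        ]
        assert congruence_dataset(pairs) == pytest.approx(0.75)
        # a zero-attention record is skipped, not averaged in
        pairs.append((np.zeros(4), np.array([1, 0, 0, 0])))
        assert congruence_dataset(pairs) == pytest.approx(0.75)
        with pytest.raises(UndefinedCongruenceError):
            congruence_dataset([(np.zeros(4), np.array([1, 0, 0, 0]))])


class TestAuroc:
    def test_perfect_separation(self):
        units = ScoredUnits([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auroc(units) == 1.0

    def test_all_ties_give_half(self):
        units = ScoredUnits(np.ones(8), [0, 1] * 4)
        assert auroc(units) == 0.5

    def test_hand_counted_example(self):
        units = ScoredUnits([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auroc(units) == pytest.approx(0.75)

    def test_matches_pair_counting_oracle_exactly_with_ties(self, rng):
        for _ in range(50):
            m = int(rng.integers(2, 400))
            # coarse quantization forces many ties
            scores = np.round(rng.uniform(0, 1, m), 1)
            labels = rng.integers(0, 2, m)
            if labels.sum() in (0, m):
                continue
            units = ScoredUnits(scores, labels)
            assert auroc(units) == pair_counting_auroc(scores, labels)

    def test_invariant_under_strictly_increasing_transform(self, rng):
        scores = rng.uniform(0, 1, 100)
        labels = rng.integers(0, 2, 100)
        a = auroc(ScoredUnits(scores, labels))
        b = auroc(ScoredUnits(np.exp(5 * scores), labels))
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateAurocError):
            auroc(ScoredUnits([0.1, 0.2], [1, 1]))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            ScoredUnits([0.1, 0.2], [1])


class TestRocCurve:
    def test_curve_endpoints_and_monotonicity(self, rng):
        units = ScoredUnits(rng.uniform(0, 1, 60), rng.integers(0, 2, 60))
        curve = roc_curve(units)
        assert curve.fpr[0] == curve.tpr[0] == 0.0
        assert curve.fpr[-1] == curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)

    def test_all_ties_curve_is_diagonal_segment(self):
        curve = roc_curve(ScoredUnits(np.ones(6), [0, 1] * 3))
        assert curve.auroc == pytest.approx(0.5)
        assert len(curve.fpr) == 2

    def test_area_matches_pair_counting(self, rng):
        for _ in range(20):
            scores = np.round(rng.uniform(0, 1, 150), 2)
            labels = rng.integers(0, 2, 150)
            if labels.sum() in (0, 150):
                continue
            units = ScoredUnits(scores, labels)
            assert roc_curve(units).auroc == pytest.approx(auroc(units), abs=1e-12)


class TestUnitConstructions:
    def test_pixel_units_pool_across_records(self, rng):
        pairs = [(rng.uniform(0, 1, 5), rng.integers(0, 2, 5)) for _ in range(2)]
        units = pixel_units(pairs)
        assert len(units) == 10

    def test_sectional_hand_example(self):
        pairs = [(np.array([0.1, 0.2, 0.9, 0.8, 0.3]), np.array([0, 0, 1, 1, 0]))]
        units = sectional_units(pairs)
        assert list(zip(units.scores, units.labels)) == [(0.2, 0), (0.9, 1), (0.3, 0)]

    def test_all_artifact_record_contributes_one_positive_unit(self):
        units = sectional_units([(np.arange(1.0, 5.0), np.ones(4, dtype=int))])
        assert len(units) == 1 and units.labels[0] == 1 and units.scores[0] == 4.0

    def test_interval_hand_tiling(self):
        pairs = [(np.array([0, 0, 5, 4, 1, 0.0]), np.array([0, 0, 1, 1, 0, 0]))]
        units = interval_units(pairs, fs=1.0, interval_len_s=2.0)
        assert list(zip(units.scores, units.labels)) == [(0.0, 0), (5.0, 1), (1.0, 0)]

    def test_default_geometry_yields_six_intervals(self):
        pairs = [(np.ones(7201), np.zeros(7201, dtype=int))]
        pairs[0][1][100] = 1
        units = interval_units(pairs, fs=240.0, interval_len_s=5.0)
        assert len(units) == 6

    def test_any_overlap_labels_interval_positive(self):
        mask = np.zeros(30, dtype=int)
        mask[25] = 1  # single annotated sample in the third 10-sample tile
        units = interval_units([(np.zeros(30), mask)], fs=1.0, interval_len_s=10.0)
        assert list(units.labels) == [0, 0, 1]

    def test_interval_longer_than_record_gives_one_unit(self, caplog):
        units = interval_units([(np.ones(20), np.r_[np.ones(5, int), np.zeros(15, int)])],
                               fs=1.0, interval_len_s=60.0)
        assert len(units) == 1


class TestAnnotationClassification:
    @staticmethod
    def _random_pairs(rng, n_records=6, n=120):
        pairs = []
        for _ in range(n_records):
            mask = np.zeros(n, dtype=int)
            a = int(rng.integers(0, n - 20))
            mask[a : a + 20] = 1
            pairs.append((mask.astype(float), mask))
        return pairs

    def test_attention_equal_to_mask_is_perfect_for_all_variants(self, rng):
        pairs = self._random_pairs(rng)
        for variant in ("pixel", "sectional", "interval"):
            assert annotation_classification(
                pairs, variant, fs=4.0, interval_len_s=5.0
            ) == pytest.approx(1.0)

    def test_uniform_attention_is_chance_for_all_variants(self, rng):
        pairs = [(np.full_like(a, 0.3), m) for a, m in self._random_pairs(rng)]
        for variant in ("pixel", "sectional", "interval"):
            assert annotation_classification(
                pairs, variant, fs=4.0, interval_len_s=5.0
            ) == pytest.approx(0.5)

    def test_independent_attention_is_near_chance(self, rng):
        # 10^4 pooled pixels, attention independent of the mask
        pairs = []
        for _ in range(10):
            mask = (rng.uniform(size=1000) < 0.4).astype(int)
            pairs.append((rng.uniform(0, 1, 1000), mask))
        assert annotation_classification(pairs, "pixel") == pytest.approx(0.5, abs=0.05)

    def test_unknown_variant_rejected(self, rng):
        with pytest.raises(ValueError):
            annotation_classification(self._random_pairs(rng), "voxel")

    def test_section_length_summary_reports_class_means(self):
        pairs = [(np.zeros(10), np.r_[np.zeros(6, int), np.ones(4, int)])]
        summary = section_length_summary(pairs)
        assert summary["mean_len_unannotated"] == 6.0
        assert summary["mean_len_annotated"] == 4.0
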
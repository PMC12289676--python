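import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from udpharm.scoring import (
    CompositeSpec,
    DegenerateColumnError,
    LesionRecord,
    composite_index,
    entropy_weights,
    lesion_score,
    minmax_normalize,
    published_composites,
    ulcer_index,
    zscore,
)

lesion_strategy = st.builds(
    LesionRecord,
    length_mm=st.floats(0, 10, allow_nan=False),
    width_mm=st.floats(0, 3, allow_nan=False),
)


class TestUlcerIndex:
    def test_no_lesions_scores_zero(self):
        assert ulcer_index([]) == 0

    @pytest.mark.parametrize(
        "length,width,expected",
        [
            (0.5, 0.2, 1),  # punctate
            (1.5, 0.5, 2),  # < 2 mm
            (2.5, 0.5, 3),  # 2-3 mm band
            (2.0, 0.5, 3),  # left band edge closed
            (3.0, 0.5, 3),  # right band edge
            (3.5, 0.5, 4),  # 3-4 mm band
            (4.0, 0.5, 4),
            (5.0, 0.5, 5),  # > 4 mm
            (2.5, 1.5, 6),  # width > 1 mm doubles
            (1.5, 1.2, 4),
        ],
    )
    def test_length_bands_and_width_doubling(self, length, width, expected):
        assert lesion_score(LesionRecord(length, width)) == expected

    def test_mixed_lesion_list(self):
        # 2 (small) + 4*2 (3-4 mm band, wide erosion) = 10
        lesions = [LesionRecord(1.5, 0.4), LesionRecord(3.5, 1.2)]
        assert ulcer_index(lesions) == 10

    def test_punctate_flag_overrides_length(self):
        assert lesion_score(LesionRecord(2.5, 0.2, punctate=True)) == 1

    @settings(deadline=None, max_examples=50)
    @given(a=st.lists(lesion_strategy, max_size=6), b=st.lists(lesion_strategy, max_size=6))
    def test_additive_over_lists(self, a, b):
        assert ulcer_index(a + b) == ulcer_index(a) + ulcer_index(b)

    def test_negative_dimension_rejected(self):
        with pytest.raises(ValueError):
            LesionRecord(-1.0, 0.5)


class TestMinMaxNormalize:
    def test_positive_orientation(self):
        assert minmax_normalize([1, 2, 3], "positive") == pytest.approx([0, 0.5, 1])

    def test_negative_orientation_reflects(self):
        assert minmax_normalize([1, 2, 3], "negative") == pytest.approx([1, 0.5, 0])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=20
        ).filter(lambda v: max(v) > min(v))
    )
    def test_orientations_sum_to_one(self, values):
        pos = minmax_normalize(values, "positive")
        neg = minmax_normalize(values, "negative")
        assert np.allclose(pos + neg, 1.0)

    def test_constant_column_rejected(self):
        with pytest.raises(DegenerateColumnError):
            minmax_normalize([2, 2, 2], "positive")


class TestEntropyWeights:
    def test_identical_columns_split_evenly(self):
        x = np.array([[0.1, 0.1], [0.5, 0.5], [0.9, 0.9]])
        assert entropy_weights(x) == pytest.approx([0.5, 0.5])

    def test_constant_column_gets_zero_weight(self):
        x = np.array([[0.5, 0.0], [0.5, 0.5], [0.5, 1.0]])
        w = entropy_weights(x)
        assert w[0] == 0.0
        assert w[1] == pytest.approx(1.0)

    def test_hand_computed_symmetric_matrix(self):
        # columns [0, .5, 1] and [1, .5, 0] have identical share entropy
        # e = -(1/ln 3)[(1/3)ln(1/3) + (2/3)ln(2/3)], so weights are equal
        x = np.array([[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]])
        w = entropy_weights(x)
        assert w == pytest.approx([0.5, 0.5], abs=1e-12)
        e = -(1 / np.log(3)) * ((1 / 3) * np.log(1 / 3) + (2 / 3) * np.log(2 / 3))
        expected = np.array([1 - e, 1 - e])
        assert w == pytest.approx(expected / expected.sum())

    def test_sums_to_one_and_permutation_equivariant(self, rng):
        x = rng.uniform(0, 1, (10, 5))
        w = entropy_weights(x)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        perm = [3, 0, 4, 1, 2]
        assert entropy_weights(x[:, perm]) == pytest.approx(w[perm])

    def test_all_constant_rejected(self):
        with pytest.raises(DegenerateColumnError):
            entropy_weights(np.full((4, 3), 0.7))


class TestCompositeIndex:
    def _mrs_table(self):
        return pd.DataFrame(
            {"UI": [0.0, 5.0, 10.0], "HS": [0.0, 2.0, 4.0]},
            index=["best", "mid", "worst"],
        )

    def test_extremes_with_published_weights(self):
        spec = CompositeSpec(
            name="MRS", components=("UI", "HS"),
            orientations={"UI": "negative", "HS": "negative"},
            weights=(0.5269, 0.4731),
        )
        scores, w = composite_index(self._mrs_table(), spec)
        assert scores["best"] == pytest.approx(1.0)  # best value of both
        assert scores["worst"] == pytest.approx(0.0)
        assert tuple(w) == (0.5269, 0.4731)

    def test_weighted_mean_at_half(self):
        # both components normalized to 0.5 -> Y = 0.5 for any weights summing to 1
        table = pd.DataFrame({"EGF": [0, 1, 2], "EGFR": [0, 2, 4]})
        spec = CompositeSpec(
            name="RF", components=("EGF", "EGFR"),
            orientations={"EGF": "positive", "EGFR": "positive"},
            weights=(0.6304, 0.3696),
        )
        scores, _ = composite_index(table, spec)
        assert scores[1] == pytest.approx(0.5)

    def test_ewm_weights_computed_when_absent(self, rng):
        table = pd.DataFrame(rng.uniform(0, 1, (12, 2)), columns=["a", "b"])
        spec = CompositeSpec(
            name="t", components=("a", "b"),
            orientations={"a": "positive", "b": "negative"},
        )
        scores, w = composite_index(table, spec)
        assert w.sum() == pytest.approx(1.0)
        assert scores.between(0, 1).all()

    def test_monotone_in_favorable_direction(self, rng):
        table = pd.DataFrame(rng.uniform(0, 1, (10, 2)), columns=["a", "b"])
        spec = CompositeSpec(
            name="t", components=("a", "b"),
            orientations={"a": "positive", "b": "negative"},
            weights=(0.6, 0.4),
        )
        base, _ = composite_index(table, spec)
        improved = table.copy()
        # improve sample 3 on 'a' without moving the min-max envelope
        mid = (table["a"].max() + table["a"][3]) / 2
        improved.loc[3, "a"] = max(mid, table["a"][3])
        new, _ = composite_index(improved, spec)
        assert new[3] >= base[3] - 1e-12

    def test_missing_component_raises(self):
        spec = CompositeSpec(
            name="t", components=("nope",), orientations={"nope": "positive"}
        )
        with pytest.raises(KeyError):
            composite_index(pd.DataFrame({"a": [1, 2]}), spec)

    def test_published_composites_load_with_unit_weight_sums(self):
        specs = published_composites()
        assert set(specs) == {"MRS", "RF", "GIC", "SIC", "LF", "HIC"}
        for spec in specs.values():
            assert abs(sum(spec.weights) - 1.0) <= 1e-4
            assert all(w >= 0 for w in spec.weights)


class TestZscore:
    def test_symmetric_triplet(self):
        assert zscore([1, 2, 3]) == pytest.approx([-1, 0, 1])

    def test_affine_invariance(self, rng):
        x = rng.normal(3, 2, 25)
        assert zscore(2.5 * x - 7) == pytest.approx(zscore(x))

    def test_output_moments(self, rng):
        z = zscore(rng.uniform(0, 10, 40))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateColumnError):
            zscore([4, 4, 4])
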
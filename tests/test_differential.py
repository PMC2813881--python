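"""Difference profiles, significance calling, region segmentation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rnafoot import (
    CallThreshold,
    ChangeCall,
    DifferenceProfile,
    call_changes,
    difference_profile,
    estimate_threshold,
    segment_regions,
    smooth,
)
from rnafoot.differential import ENHANCEMENT, PROTECTION


def _react(vals, mask=None, smoothed=False):
    from rnafoot import ReactivityProfile

    vals = np.asarray(vals, dtype=float)
    n = len(vals)
    return ReactivityProfile(
        positions=np.arange(1, n + 1),
        reactivity=vals,
        nodata_mask=np.zeros(n, dtype=bool) if mask is None else np.asarray(mask, bool),
        normalization_factor=1.0,
        smoothed=smoothed,
    )


def _diff(deltas, mask=None):
    deltas = np.asarray(deltas, dtype=float)
    n = len(deltas)
    return DifferenceProfile(
        positions=np.arange(1, n + 1),
        delta=deltas,
        nodata_mask=np.zeros(n, dtype=bool) if mask is None else np.asarray(mask, bool),
    )


class TestDifferenceProfile:
    def test_identical_profiles_give_zero(self, rng):
        v = rng.uniform(0, 1.5, 40)
        d = difference_profile(_react(v), _react(v))
        np.testing.assert_array_equal(d.delta, 0.0)

    def test_protection_sign_convention(self):
        d = difference_profile(_react([0.7]), _react([1.0]))
        assert d.delta[0] == pytest.approx(-0.3)

    def test_masks_are_unioned(self):
        d = difference_profile(
            _react([1, 1, 1], mask=[True, False, False]),
            _react([1, 1, 1], mask=[False, True, False]),
        )
        assert list(d.nodata_mask) == [True, True, False]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            difference_profile(_react([1, 2]), _react([1, 2, 3]))

    def test_mixed_smoothing_states_rejected(self):
        with pytest.raises(ValueError, match="smooth"):
            difference_profile(_react([1.0], smoothed=True), _react([1.0]))

    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _react(rng.uniform(0, 1.5, 25)), _react(rng.uniform(0, 1.5, 25))
        np.testing.assert_allclose(
            difference_profile(a, b).delta, -difference_profile(b, a).delta
        )

    def test_footprints_dominate_simulated_differences(
        self, toy_model, free_bound_reactivity
    ):
        free, bound = free_bound_reactivity
        d = difference_profile(smooth(bound), smooth(free))
        fp = np.array(toy_model.footprint_positions()) - 1
        rest = np.setdiff1d(np.arange(toy_model.length), fp)
        assert np.nanmean(d.delta[fp]) < -0.3
        assert abs(np.nanmean(d.delta[rest])) < 0.05


class TestEstimateThreshold:
    def test_two_fold_above_mean_background(self):
        # mean |delta| of 0.1 over replicates -> threshold 0.2
        reps = [_diff(np.full(50, 0.1)), _diff(np.full(50, -0.1))]
        t = estimate_threshold(reps, multiplier=2)
        assert t.min_abs_delta == pytest.approx(0.2)

    def test_no_replicates_falls_back_to_default(self):
        assert estimate_threshold([]).min_abs_delta == 0.2

    def test_strict_mode_requires_replicates(self):
        with pytest.raises(ValueError, match="strict"):
            estimate_threshold([], strict=True)

    def test_zero_background_gives_degenerate_zero_threshold(self):
        t = estimate_threshold([_diff(np.zeros(30))])
        assert t.min_abs_delta == 0.0
        with pytest.raises(ValueError):  # degenerate threshold cannot call
            call_changes(_diff([0.5]), t)

    def test_matches_direct_summation_oracle(self, rng):
        deltas = rng.normal(0, 0.1, 20)
        t = estimate_threshold([_diff(deltas)], multiplier=2)
        oracle = 2 * sum(abs(x) for x in deltas.tolist()) / 20
        assert t.min_abs_delta == pytest.approx(oracle)


class TestCallChanges:
    def test_boundary_is_inclusive_at_exactly_0_2(self):
        calls = call_changes(_diff([-0.19, -0.20, -0.21]))
        assert [c.position for c in calls] == [2, 3]
        assert all(c.direction == PROTECTION for c in calls)

    def test_all_zero_profile_yields_no_calls(self):
        assert call_changes(_diff(np.zeros(30))) == []

    def test_direction_follows_sign(self):
        calls = call_changes(_diff([-0.5, 0.5]))
        assert [c.direction for c in calls] == [PROTECTION, ENHANCEMENT]

    def test_masked_positions_never_called(self):
        calls = call_changes(_diff([-0.5, -0.5], mask=[True, False]))
        assert [c.position for c in calls] == [2]

    def test_injected_footprint_called_in_over_95_percent_of_replicates(self):
        # E[delta] = -0.4, noise sd 0.05: each footprint nucleotide clears the
        # 0.2 rule except in the extreme noise tail
        n_fp, hits, total = 10, 0, 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            deltas = rng.normal(0, 0.05, 100)
            deltas[40:50] += -0.4
            calls = {c.position for c in call_changes(_diff(deltas))}
            hits += sum(1 for p in range(41, 51) if p in calls)
            total += n_fp
        assert hits / total >= 0.95

    def test_calls_invariant_to_common_additive_shift(self, rng):
        a, b = _react(rng.uniform(0, 1.5, 40)), _react(rng.uniform(0, 1.5, 40))
        calls1 = call_changes(difference_profile(a, b))
        shifted = difference_profile(_react(a.reactivity + 0.3), _react(b.reactivity + 0.3))
        calls2 = call_changes(shifted)
        assert [(c.position, c.direction) for c in calls1] == [
            (c.position, c.direction) for c in calls2
        ]

    def test_false_call_rate_stable_when_background_mean_is_0_1(self):
        # Gaussian deltas with mean |delta| = 0.1 (sigma = 0.1 * sqrt(pi/2));
        # the per-nucleotide false-call rate at |delta| >= 0.2 must sit in a
        # stable band across seeds
        sigma = 0.1 * np.sqrt(np.pi / 2)
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            deltas = rng.normal(0, sigma, 500)
            assert np.mean(np.abs(deltas)) == pytest.approx(0.1, abs=0.015)
            rates.append(len(call_changes(_diff(deltas))) / 500)
        assert all(0.05 <= r <= 0.18 for r in rates)


class TestSegmentRegions:
    def _calls(self, layout):
        return [ChangeCall(p, d, 0.3) for p, d in layout]

    def test_contiguous_same_direction_is_one_region(self):
        regions = segment_regions(self._calls([(10, PROTECTION), (11, PROTECTION), (12, PROTECTION)]))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (10, 12)

    def test_direction_change_splits_region(self):
        regions = segment_regions(
            self._calls([(10, PROTECTION), (11, PROTECTION), (12, ENHANCEMENT)])
        )
        assert len(regions) == 2

    def test_max_gap_semantics(self):
        calls = self._calls([(10, PROTECTION), (13, PROTECTION)])
        assert len(segment_regions(calls, max_gap=1)) == 2
        assert len(segment_regions(calls, max_gap=3)) == 1

    def test_unsorted_calls_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            segment_regions(self._calls([(13, PROTECTION), (10, PROTECTION)]))

    def test_region_mean_magnitude(self):
        regions = segment_regions(
            [ChangeCall(5, PROTECTION, 0.2), ChangeCall(6, PROTECTION, 0.4)]
        )
        assert regions[0].mean_magnitude == pytest.approx(0.3)
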
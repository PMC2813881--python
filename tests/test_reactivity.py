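"""Background subtraction, normalization, smoothing, accessibility calls."""

from math import ceil

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rnafoot import (
    CleavageProfile,
    NormalizationRule,
    SimulationConfig,
    classify_inaccessible,
    normalize_reactivity,
    simulate_cleavage,
    smooth,
    subtract_background,
)


def _profile(plus, minus=None, mask=None):
    plus = np.asarray(plus, dtype=float)
    n = len(plus)
    return CleavageProfile(
        positions=np.arange(1, n + 1),
        plus_intensity=plus,
        minus_intensity=np.zeros(n) if minus is None else np.asarray(minus, dtype=float),
        nodata_mask=np.zeros(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool),
    )


class TestSubtractBackground:
    def test_zero_minus_channel_is_identity(self, rng):
        plus = rng.uniform(0, 100, 50)
        net = subtract_background(_profile(plus))
        np.testing.assert_array_equal(net.plus_intensity, plus)

    def test_equal_channels_give_zero(self, rng):
        v = rng.uniform(0, 100, 50)
        net = subtract_background(_profile(v, v))
        np.testing.assert_array_equal(net.plus_intensity, 0.0)

    def test_floor_at_zero(self):
        net = subtract_background(_profile([5.0], [20.0]))
        assert net.plus_intensity[0] == 0.0

    def test_saturated_minus_positions_masked(self):
        net = subtract_background(_profile([10, 10], [1, 9000]), saturation_level=8000)
        assert list(net.nodata_mask) == [False, True]

    def test_generator_background_cancels_exactly_without_noise(self, toy_model):
        base = dict(noise_cv=0.0, intensity_scale=1000.0)
        with_bg = simulate_cleavage(toy_model, "free", SimulationConfig(seed=4, background_rate=0.1, **base))
        no_bg = simulate_cleavage(toy_model, "free", SimulationConfig(seed=4, background_rate=0.0, **base))
        net = subtract_background(with_bg)
        np.testing.assert_allclose(net.plus_intensity, no_bg.plus_intensity, atol=1e-9)

    def test_generator_background_within_noise_of_clean_simulation(self, toy_model):
        # same seed draws the same signal noise, so the residual is only the
        # difference of the two independent background draws
        cv, bg, scale = 0.05, 0.1, 1000.0
        with_bg = simulate_cleavage(
            toy_model, "free", SimulationConfig(seed=4, noise_cv=cv, background_rate=bg)
        )
        no_bg = simulate_cleavage(
            toy_model, "free", SimulationConfig(seed=4, noise_cv=cv, background_rate=0.0)
        )
        net = subtract_background(with_bg)
        resid = net.plus_intensity - no_bg.plus_intensity
        sd = cv * bg * scale * np.sqrt(2)  # sd of the background-difference term
        assert np.max(np.abs(resid)) < 6 * sd


class TestNormalize:
    def test_equal_values_normalize_to_one(self):
        r = normalize_reactivity(_profile(np.full(100, 37.0)))
        np.testing.assert_allclose(r.reactivity, 1.0)
        assert r.normalization_factor == pytest.approx(37.0)

    def test_reference_set_mean_is_exactly_one(self, toy_model):
        raw = simulate_cleavage(toy_model, "free", SimulationConfig(seed=8))
        r = normalize_reactivity(subtract_background(raw))
        ref = np.isin(r.positions, r.reference_positions)
        assert np.mean(r.reactivity[ref]) == pytest.approx(1.0, abs=1e-12)

    def test_factor_matches_hand_sort_and_average_oracle(self, rng):
        values = rng.uniform(1, 500, 50)
        r = normalize_reactivity(_profile(values))
        # independent oracle: plain python sort, drop ceil(2%), average next ceil(8%)
        ordered = sorted(values.tolist(), reverse=True)
        n_excl, n_ref = ceil(0.02 * 50), ceil(0.08 * 50)
        oracle = sum(ordered[n_excl : n_excl + n_ref]) / n_ref
        assert r.normalization_factor == pytest.approx(oracle)
        np.testing.assert_allclose(r.reactivity, values / oracle)

    def test_too_few_unmasked_positions_rejected(self):
        with pytest.raises(ValueError, match="25"):
            normalize_reactivity(_profile(np.ones(20)))

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_reactivity(_profile(np.zeros(100)))

    def test_masked_positions_excluded_from_statistics(self, rng):
        values = rng.uniform(1, 100, 60)
        mask = np.zeros(60, dtype=bool)
        mask[:10] = True
        values[:10] = 1e9  # huge but masked: must not affect the factor
        r = normalize_reactivity(_profile(values, mask=mask))
        ordered = sorted(values[10:].tolist(), reverse=True)
        n_excl, n_ref = ceil(0.02 * 50), ceil(0.08 * 50)
        assert r.normalization_factor == pytest.approx(
            sum(ordered[n_excl : n_excl + n_ref]) / n_ref
        )
        assert np.all(np.isnan(r.reactivity[:10]))

    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(99)
        values = rng.uniform(1, 100, 80)
        a = normalize_reactivity(_profile(values))
        b = normalize_reactivity(_profile(values * scale))
        np.testing.assert_allclose(a.reactivity, b.reactivity, rtol=1e-10)

    def test_idempotence_on_own_output(self, rng):
        values = rng.uniform(1, 100, 80)
        a = normalize_reactivity(_profile(values))
        b = normalize_reactivity(_profile(a.reactivity))
        np.testing.assert_allclose(a.reactivity, b.reactivity, rtol=1e-12)


class TestSmooth:
    def _react(self, vals, mask=None):
        vals = np.asarray(vals, dtype=float)
        from rnafoot import ReactivityProfile

        n = len(vals)
        return ReactivityProfile(
            positions=np.arange(1, n + 1),
            reactivity=vals,
            nodata_mask=np.zeros(n, dtype=bool) if mask is None else np.asarray(mask, bool),
            normalization_factor=1.0,
        )

    def test_constant_profile_unchanged(self):
        s = smooth(self._react(np.full(10, 0.7)), 3)
        np.testing.assert_allclose(s.reactivity, 0.7)

    def test_center_of_spike_is_window_mean(self):
        s = smooth(self._react([0.0, 3.0, 0.0]), 3)
        assert s.reactivity[1] == pytest.approx(1.0)

    def test_window_shrinks_at_sequence_ends(self):
        s = smooth(self._react([2.0, 4.0, 4.0, 4.0]), 3)
        assert s.reactivity[0] == pytest.approx(3.0)  # two-term window

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth(self._react([1.0, 2.0, 3.0]), 2)

    def test_masked_positions_excluded_and_stay_masked(self):
        mask = np.array([False, True, False])
        s = smooth(self._react([1.0, 100.0, 3.0], mask), 3)
        assert np.isnan(s.reactivity[1])
        assert s.reactivity[0] == pytest.approx(1.0)  # masked neighbor dropped
        assert s.reactivity[2] == pytest.approx(3.0)

    @given(st.lists(st.floats(min_value=0, max_value=2), min_size=3, max_size=40))
    def test_output_stays_within_input_range(self, vals):
        s = smooth(self._react(vals), 3)
        assert np.all(s.reactivity >= min(vals) - 1e-12)
        assert np.all(s.reactivity <= max(vals) + 1e-12)

    def test_mean_preserved_over_interior_region_with_flat_flanks(self, rng):
        # exact when the flanking values equal the region's edge values
        region = rng.uniform(0, 2, 30)
        vals = np.concatenate([[region[0]], region, [region[-1]]])
        s = smooth(self._react(vals), 3)
        assert np.mean(s.reactivity[1:-1]) == pytest.approx(np.mean(region))


class TestClassifyInaccessible:
    def _react(self, vals):
        from rnafoot import ReactivityProfile

        vals = np.asarray(vals, dtype=float)
        return ReactivityProfile(
            positions=np.arange(1, len(vals) + 1),
            reactivity=vals,
            nodata_mask=np.zeros(len(vals), dtype=bool),
            normalization_factor=1.0,
        )

    def test_cutoff_is_inclusive(self):
        flags = classify_inaccessible(self._react([0.5, 0.51, 0.49, 1.2]))
        assert list(flags) == [True, False, True, False]

    def test_flagged_fraction_matches_generator_ground_truth(self, toy_model):
        # toy free state buries ~20% of nucleotides; the classifier must
        # recover that fraction within 5 percentage points
        raw = simulate_cleavage(toy_model, "free", SimulationConfig(seed=21))
        r = normalize_reactivity(subtract_background(raw))
        flagged = classify_inaccessible(r).mean()
        truth = np.mean(toy_model.accessibility_free < 0.5)
        assert truth == pytest.approx(0.2, abs=0.01)
        assert abs(flagged - truth) <= 0.05
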
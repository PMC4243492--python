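"""Visual hierarchy: construction, feedforward, priming, suppression, IOR."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stcp.hierarchy import (
    BiasSpec,
    HierarchyConfig,
    PoolSpec,
    build_hierarchy,
)
from stcp.image import ChannelImage
from stcp.wta import AttentionalSample

from .conftest import random_image


class TestConstruction:
    def test_four_levels_stride_two_shrinks_64_to_8(self):
        cfg = HierarchyConfig(input_shape=(64, 64), channels=("x",))
        vh = build_hierarchy(cfg)
        assert vh.n_levels == 4
        assert vh.level_shape(0) == (64, 64)
        assert vh.level_shape(3) == (8, 8)

    def test_central_radius_in_pixels(self):
        cfg = HierarchyConfig(
            input_shape=(64, 64), channels=("x",), central_radius_deg=10.0,
            deg_per_pixel=0.5,
        )
        assert cfg.central_radius_px == 20.0

    def test_fresh_hierarchy_has_neutral_state(self, small_vh):
        for level in small_vh.suppression:
            for arr in level.values():
                assert (arr == 1.0).all()
        for l in range(small_vh.n_levels):
            for ch in small_vh.config.channels:
                assert not small_vh.inhibited(l, ch).any()

    def test_inconsistent_resolution_rejected(self):
        with pytest.raises(ValueError):
            HierarchyConfig(input_shape=(63, 64), channels=("x",))

    def test_fewer_than_three_levels_rejected(self):
        with pytest.raises(ValueError):
            HierarchyConfig(input_shape=(16, 16), channels=("x",), pools=(PoolSpec(),))


class TestFeedforward:
    def test_blank_image_yields_zero_everywhere(self, small_vh):
        acts = small_vh.feedforward(ChannelImage.blank(("a", "b"), (16, 16)))
        for level in acts.levels:
            for plane in level.values():
                assert (plane == 0).all()

    def test_unit_impulse_hand_propagation(self, small_vh):
        # one unit input at (0, 0); each 2x2 mean divides by 4: top value 1/16
        img = ChannelImage.blank(("a", "b"), (16, 16))
        img["a"][0, 0] = 1.0
        acts = small_vh.feedforward(img)
        assert acts.levels[1]["a"][0, 0] == pytest.approx(1 / 4)
        assert acts.levels[2]["a"][0, 0] == pytest.approx(1 / 16)
        assert acts.levels[2]["a"].sum() == pytest.approx(1 / 16)
        assert (acts.levels[2]["b"] == 0).all()

    def test_resolution_mismatch_rejected(self, small_vh):
        with pytest.raises(ValueError):
            small_vh.feedforward(ChannelImage.blank(("a", "b"), (8, 8)))

    def test_pooling_is_permutation_invariant_within_windows(self, small_vh, rng):
        # a mean pool cannot care about the arrangement inside one window --
        # the signature of a non-selecting (no-max) feedforward stage
        img = random_image(rng)
        acts1 = small_vh.feedforward(img)
        shuffled = img.copy()
        window = shuffled["a"][0:2, 0:2].ravel()
        shuffled["a"][0:2, 0:2] = window[::-1].reshape(2, 2)
        acts2 = small_vh.feedforward(shuffled)
        assert np.allclose(acts1.levels[1]["a"], acts2.levels[1]["a"])

    @given(st.floats(0.1, 3.0), st.floats(0.1, 3.0))
    def test_linearity_probe(self, a, b):
        rng = np.random.default_rng(99)
        cfg = HierarchyConfig(
            input_shape=(16, 16), channels=("a", "b"),
            pools=(PoolSpec(2, 2), PoolSpec(2, 2)),
        )
        vh = build_hierarchy(cfg)
        i1, i2 = random_image(rng), random_image(rng)
        combo = ChannelImage(("a", "b"), a * i1.data + b * i2.data)
        acts1 = vh.feedforward(i1)
        acts2 = vh.feedforward(i2)
        acts = vh.feedforward(combo)
        for l in range(vh.n_levels):
            for ch in ("a", "b"):
                assert np.allclose(
                    acts.levels[l][ch],
                    a * acts1.levels[l][ch] + b * acts2.levels[l][ch],
                )


class TestPriming:
    def test_channel_gain_doubles_responses_everywhere(self, small_config, rng):
        img = random_image(rng)
        plain = build_hierarchy(small_config).feedforward(img)
        primed_vh = build_hierarchy(small_config)
        primed_vh.apply_priming(BiasSpec(channel_gains={"a": 2.0}))
        primed = primed_vh.feedforward(img)
        for l in range(3):
            assert np.allclose(primed.levels[l]["a"], 2.0 * plain.levels[l]["a"])
            assert np.array_equal(primed.levels[l]["b"], plain.levels[l]["b"])

    def test_empty_bias_is_identity(self, small_vh, rng):
        img = random_image(rng)
        before = small_vh.feedforward(img)
        small_vh.apply_priming(BiasSpec())
        after = small_vh.feedforward(img)
        for l in range(3):
            assert np.array_equal(before.levels[l]["a"], after.levels[l]["a"])

    def test_unknown_channel_error_names_it(self, small_vh):
        with pytest.raises(KeyError, match="nope"):
            small_vh.apply_priming(BiasSpec(channel_gains={"nope": 2.0}))

    def test_priming_event_leads_stimulus_onset(self, small_vh):
        from stcp.events import EventLog, ModelClock

        clock, log = ModelClock(), EventLog()
        small_vh.apply_priming(BiasSpec(channel_gains={"a": 1.5}), clock=clock, log=log)
        onset = clock.now_ms
        prime_event = log.filter(event="stage")[0]
        assert prime_event.payload["stage"] == "B"
        assert onset - prime_event.t_ms == clock.costs.priming_lead_ms == 150.0


def _sample_at(vh, level_units):
    """Helper: a minimal attentional sample from {level: {(ch, r, c)}}."""
    top = max(level_units)
    any_unit = next(iter(level_units[top]))
    return AttentionalSample(
        root=(top, any_unit[1], any_unit[2]),
        levels={l: frozenset(units) for l, units in level_units.items()},
    )


class TestSuppression:
    def test_zero_factor_annulus_erases_contribution(self, small_vh, rng):
        img = random_image(rng)
        sample = _sample_at(small_vh, {1: {("a", 4, 4)}, 2: {("a", 2, 2)}})
        small_vh.suppress_level(0, {"a": {(8, 8)}}, extent=1, factor=0.0)
        acts = small_vh.feedforward(img)
        # window (8..10, 8..10) of level-1 unit (4,4) contains suppressed units
        clean = build_hierarchy(small_vh.config).feedforward(img)
        assert acts.levels[1]["a"][4, 4] != pytest.approx(clean.levels[1]["a"][4, 4])

    def test_selected_units_never_suppressed(self, small_vh):
        small_vh.suppress_level(1, {"a": {(3, 3), (3, 4)}}, extent=2, factor=0.1)
        assert small_vh.suppression[1]["a"][3, 3] == 1.0
        assert small_vh.suppression[1]["a"][3, 4] == 1.0
        assert small_vh.suppression[1]["a"][3, 5] == pytest.approx(0.1)

    def test_sibling_feature_suppressed_at_selected_locations(self, small_vh):
        small_vh.suppress_level(1, {"a": {(3, 3)}}, extent=1, factor=0.2,
                                feature_channels=("b",))
        assert small_vh.suppression[1]["b"][3, 3] == pytest.approx(0.2)
        assert small_vh.suppression[1]["a"][3, 3] == 1.0

    def test_factor_out_of_range_rejected(self, small_vh):
        with pytest.raises(ValueError):
            small_vh.suppress_level(0, {"a": {(0, 0)}}, factor=1.0)

    def test_lift_restores_fresh_state_and_is_idempotent(self, small_vh, rng):
        img = random_image(rng)
        small_vh.suppress_level(0, {"a": {(4, 4)}}, extent=2, factor=0.3)
        small_vh.lift_surround_suppression()
        for level in small_vh.suppression:
            for arr in level.values():
                assert (arr == 1.0).all()
        acts = small_vh.feedforward(img)
        clean = build_hierarchy(small_vh.config).feedforward(img)
        for l in range(3):
            assert np.array_equal(acts.levels[l]["a"], clean.levels[l]["a"])
        small_vh.lift_surround_suppression()  # no-op on fresh state

    def test_state_separation_lift_keeps_priming_and_inhibition(self, small_vh):
        small_vh.apply_priming(BiasSpec(channel_gains={"a": 3.0}))
        sample = _sample_at(small_vh, {2: {("a", 1, 1)}})
        small_vh.inhibit_pathways(sample)
        small_vh.suppress_level(1, {"a": {(2, 2)}}, factor=0.5)
        small_vh.lift_surround_suppression()
        assert small_vh.gains[0]["a"][0, 0] == 3.0
        assert small_vh.inhibited(2, "a")[1, 1]


class TestPathwayInhibition:
    def test_inhibited_unit_contributes_zero_above(self, small_vh, rng):
        img = random_image(rng)
        clean = small_vh.feedforward(img)
        sample = _sample_at(small_vh, {0: {("a", 0, 0)}, 1: {("a", 0, 0)}})
        small_vh.inhibit_pathways(sample)
        acts = small_vh.feedforward(img)
        # (0,0) at level 0 feeds level-1 (0,0): its contribution is gone
        expected = clean.levels[1]["a"][0, 0] - img["a"][0, 0] / 4
        # level-1 (0,0) is itself inhibited too, so check level 2 instead
        assert acts.levels[2]["a"][0, 0] == pytest.approx(
            clean.levels[2]["a"][0, 0] - clean.levels[1]["a"][0, 0] / 4
        )
        # untouched branches identical
        assert np.array_equal(acts.levels[1]["a"][4:], clean.levels[1]["a"][4:])

    def test_flags_expire_after_horizon(self, small_vh):
        sample = _sample_at(small_vh, {2: {("a", 0, 0)}})
        small_vh.inhibit_pathways(sample)
        horizon = small_vh.config.ior_horizon_cycles
        assert small_vh.inhibited(2, "a")[0, 0]
        for _ in range(horizon):
            small_vh.advance_cycle()
        assert not small_vh.inhibited(2, "a")[0, 0]

    def test_empty_sample_is_a_no_op(self, small_vh):
        sample = AttentionalSample(root=(2, 0, 0), levels={2: frozenset()})
        small_vh.inhibit_pathways(sample)
        for l in range(small_vh.n_levels):
            for ch in ("a", "b"):
                assert not small_vh.inhibited(l, ch).any()
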
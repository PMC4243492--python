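"""Fixation control: PPM, pFOA, FHM, HBPM, saccades."""

import numpy as np
import pytest

from stcp.events import EventLog, ModelClock, SequencingError
from stcp.fixation import (
    FHM,
    Fixation,
    Gaze,
    PPM,
    compose_hbpm,
    compute_ppm,
    execute_saccade,
    select_next_fixation,
    select_pfoa,
)
from stcp.hierarchy import BiasSpec
from stcp.image import ChannelImage


def item_image(positions, shape=(64, 64), values=None, channels=("colorA",)):
    img = ChannelImage.blank(channels, shape)
    for i, (r, c) in enumerate(positions):
        v = values[i] if values else 1.0
        img[channels[0]][r - 1 : r + 2, c - 1 : c + 2] = v
    return img


class TestPPM:
    @pytest.mark.parametrize("seed", range(10))
    def test_central_zero_for_random_images(self, seed):
        rng = np.random.default_rng(seed)
        img = ChannelImage(("a", "b"), rng.uniform(size=(2, 64, 64)))
        ppm = compute_ppm(img, central_radius_px=20.0)
        rr = np.arange(64)[:, None] - 32
        cc = np.arange(64)[None, :] - 32
        assert (ppm.grid[rr**2 + cc**2 <= 400.0] == 0).all()

    def test_uniform_image_has_zero_saliency(self):
        img = ChannelImage(("a",), np.full((1, 64, 64), 0.7))
        ppm = compute_ppm(img, central_radius_px=10.0)
        assert np.allclose(ppm.grid, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_single_peripheral_item_is_the_unique_peak(self, seed):
        rng = np.random.default_rng(1000 + seed)
        ang = rng.uniform(0, 2 * np.pi)
        pos = (int(32 + 27 * np.sin(ang)), int(32 + 27 * np.cos(ang)))
        img = item_image([pos])
        ppm = compute_ppm(img, central_radius_px=20.0)
        peak = np.unravel_index(np.argmax(ppm.grid), ppm.grid.shape)
        assert max(abs(peak[0] - pos[0]), abs(peak[1] - pos[1])) <= 2

    def test_bias_weights_channels(self):
        img = ChannelImage.blank(("a", "b"), (64, 64))
        img["a"][10, 10] = 1.0
        img["b"][10, 50] = 1.0
        ppm = compute_ppm(img, BiasSpec(channel_gains={"a": 3.0}), central_radius_px=5.0)
        assert ppm.grid[10, 10] > ppm.grid[10, 50]


class TestPfoa:
    def test_zero_map_gives_empty_list(self):
        assert select_pfoa(PPM(np.zeros((32, 32)), 0.0), k=3) == []

    def test_two_equal_peaks_ordered_by_tiebreak(self):
        grid = np.zeros((32, 32))
        grid[5, 5] = grid[20, 20] = 1.0
        peaks = select_pfoa(PPM(grid, 0.0), k=2, exclusion_radius=3)
        assert [p for _, p in peaks] == [(5, 5), (20, 20)]

    def test_graded_items_ranked_strongest_first(self):
        positions = [(8, 8), (8, 40), (40, 8), (40, 40), (24, 50)]
        values = [0.9, 0.7, 0.5, 0.3, 0.1]
        img = item_image(positions, values=values)
        ppm = compute_ppm(img, central_radius_px=2.0)
        peaks = select_pfoa(ppm, k=3, exclusion_radius=5)
        got = [p for _, p in peaks]
        for want, have in zip(positions[:3], got):
            assert max(abs(want[0] - have[0]), abs(want[1] - have[1])) <= 2


class TestFHM:
    def test_three_updates_decay_to_lambda_cubed(self):
        fhm = FHM(lam=0.5, eps=0.0)
        fhm.update((0, 0))
        for i in range(3):
            fhm.update((i + 1, 0))
        assert fhm.entries[0].weight == pytest.approx(0.125)

    def test_entry_survives_exactly_six_further_updates(self):
        # 0.5**6 = 0.015625 >= 0.01 > 0.5**7
        fhm = FHM(lam=0.5, eps=0.01)
        fhm.update((0, 0))
        for i in range(6):
            fhm.update((i + 1, 0))
            assert fhm.entries[0].world_pos == (0, 0)
        fhm.update((9, 9))
        assert fhm.entries[0].world_pos != (0, 0)

    def test_world_positions_invariant_under_saccades(self):
        fhm = FHM(lam=1.0, eps=0.0)
        gaze = Gaze((160, 160), (64, 64), fixation=(80, 80))
        fhm.update((70, 75))
        before_ret = gaze.world_to_retina((70, 75))
        gaze.saccade_to((90, 95))  # displacement (+10, +15)
        after_ret = gaze.world_to_retina((70, 75))
        assert fhm.entries[0].world_pos == (70, 75)
        assert (before_ret[0] - after_ret[0], before_ret[1] - after_ret[1]) == (10, 15)

    def test_inhibition_covers_disk_and_traced_pixels(self):
        fhm = FHM(lam=1.0, eps=0.0)
        gaze = Gaze((64, 64), (64, 64), fixation=(32, 32))
        fhm.update((10, 10), traced=frozenset({(50, 50)}))
        inh = fhm.inhibition(gaze, radius_px=3.0)
        assert inh[10, 10] == 1.0
        assert inh[50, 50] == 1.0
        assert inh[30, 30] == 0.0


class TestHBPM:
    def _ppm(self):
        grid = np.zeros((64, 64))
        grid[10, 10] = 1.0
        grid[50, 50] = 0.8
        return PPM(grid, 0.0)

    def test_full_weight_entry_zeroes_priority(self):
        gaze = Gaze((64, 64), (64, 64), fixation=(32, 32))
        fhm = FHM(lam=1.0, eps=0.0)
        fhm.update((10, 10))
        hbpm = compose_hbpm(self._ppm(), None, [(1.0, (10, 10))], fhm, gaze,
                            inhibit_radius_px=3.0)
        assert hbpm.grid[10, 10] == 0.0
        assert hbpm.grid[50, 50] == pytest.approx(0.8)

    def test_no_history_equals_raw_ppm(self):
        gaze = Gaze((64, 64), (64, 64))
        hbpm = compose_hbpm(self._ppm(), (32, 32), [], FHM(), gaze)
        assert np.array_equal(hbpm.grid, self._ppm().grid)

    def test_override_ignores_history(self):
        gaze = Gaze((64, 64), (64, 64))
        fhm = FHM(lam=1.0, eps=0.0)
        fhm.update((10, 10))
        hbpm = compose_hbpm(self._ppm(), None, [(1.0, (10, 10))], fhm, gaze,
                            inhibit_radius_px=3.0, override_ior=True)
        assert hbpm.grid[10, 10] == pytest.approx(1.0)

    def test_requires_some_focus(self):
        gaze = Gaze((64, 64), (64, 64))
        with pytest.raises(ValueError):
            compose_hbpm(self._ppm(), None, [], FHM(), gaze)


class TestNextFixationAndSaccade:
    def test_single_candidate_above_floor_is_chosen(self):
        gaze = Gaze((64, 64), (64, 64))
        grid = np.zeros((64, 64))
        grid[40, 12] = 0.5
        from stcp.fixation import HBPM

        fix = select_next_fixation(HBPM(grid), gaze)
        assert fix.pos == (40, 12)

    def test_everything_inhibited_yields_none(self):
        gaze = Gaze((64, 64), (64, 64))
        from stcp.fixation import HBPM

        assert select_next_fixation(HBPM(np.zeros((64, 64))), gaze) is None

    def test_constraint_filters_candidates(self):
        gaze = Gaze((64, 64), (64, 64))
        grid = np.zeros((64, 64))
        grid[10, 10] = 1.0
        grid[50, 50] = 0.6
        from stcp.fixation import HBPM

        fix = select_next_fixation(
            HBPM(grid), gaze, constraint=lambda p: p[0] > 30
        )
        assert fix.pos == (50, 50)

    def test_identity_view_when_world_equals_retina(self):
        world = ChannelImage(("a",), np.arange(64 * 64, dtype=float).reshape(1, 64, 64))
        gaze = Gaze((64, 64), (64, 64), fixation=(32, 32))
        assert np.array_equal(gaze.view(world).data, world.data)

    def test_edge_fixation_zero_pads_expected_margin(self):
        world = ChannelImage(("a",), np.ones((1, 64, 64)))
        gaze = Gaze((64, 64), (64, 64), fixation=(32, 5))
        view = gaze.view(world)
        assert (view["a"][:, :27] == 0).all()  # origin col = 5-32 = -27
        assert (view["a"][:, 27:] == 1).all()

    def test_saccade_without_disengage_is_a_sequencing_error(self):
        world = ChannelImage(("a",), np.ones((1, 128, 128)))
        gaze = Gaze((128, 128), (64, 64))
        log, clock = EventLog(), ModelClock()
        log.record(0.0, "vAE", "cycle_start", cycle=0)
        with pytest.raises(SequencingError):
            execute_saccade(gaze, Fixation(70, 70), world, log=log, clock=clock)
        log.record(0.0, "vAE", "disengage")
        execute_saccade(gaze, Fixation(70, 70), world, log=log, clock=clock)
        assert gaze.fixation == (70, 70)

    def test_return_saccade_blocked_until_decay_elapses(self):
        # two targets A and B; after A -> B with undecayed IOR, B -> A is not
        # selectable; once the history has decayed it is again
        gaze = Gaze((64, 64), (64, 64), fixation=(32, 32))
        grid = np.zeros((64, 64))
        grid[10, 10] = 1.0  # A
        grid[50, 50] = 0.9  # B
        from stcp.fixation import HBPM

        fhm = FHM(lam=0.5, eps=0.0)
        fhm.update((10, 10))  # we were at A; moving to B
        hbpm = compose_hbpm(PPM(grid, 0.0), None, [(1.0, (10, 10))], fhm, gaze,
                            inhibit_radius_px=3.0)
        fix = select_next_fixation(hbpm, gaze, floor_frac=0.2)
        assert fix.pos == (50, 50)
        # immediately trying to go back: A's entry is at full weight, so its
        # priority is zero and (excluding the current fixation) nothing wins
        hbpm2 = compose_hbpm(PPM(grid, 0.0), None, [(1.0, (10, 10))], fhm, gaze,
                             inhibit_radius_px=3.0)
        assert hbpm2.grid[10, 10] == 0.0
        assert select_next_fixation(
            hbpm2, gaze, floor_frac=0.2, constraint=lambda p: p != (50, 50)
        ) is None
        # let the history decay: A's weight shrinks by lam per update
        for i in range(7):
            fhm.update((50, 50))
        hbpm3 = compose_hbpm(PPM(grid, 0.0), None, [(1.0, (10, 10))], fhm, gaze,
                             inhibit_radius_px=3.0)
        fix3 = select_next_fixation(hbpm3, gaze, floor_frac=0.2,
                                    constraint=lambda p: p != (50, 50))
        assert fix3.pos == (10, 10)
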
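import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hccimg import events as ev
from hccimg import simulator as sim

from conftest import make_hits


class TestCoincidenceGrouping:
    def test_separated_hits_form_two_events(self):
        hits = make_hits([(0.0, 0, "front", 1, 1, 100.0),
                          (50.0, 0, "rear", 1, 1, 100.0),
                          (1000.0, 1, "rear", 2, 2, 60.0)])
        out = ev.group_coincidences(hits, 100.0)
        assert out["event_id"].tolist() == [0, 0, 1]

    def test_window_anchored_at_opener_not_last_hit(self):
        hits = make_hits([(0.0, 0, "front", 1, 1, 10.0),
                          (90.0, 0, "rear", 1, 1, 10.0),
                          (180.0, 0, "rear", 2, 2, 10.0)])
        out = ev.group_coincidences(hits, 100.0)
        assert out["event_id"].tolist() == [0, 0, 1]

    def test_empty_input(self):
        out = ev.group_coincidences(make_hits([]))
        assert len(out) == 0 and "event_id" in out.columns

    def test_unsorted_input_rejected(self):
        hits = make_hits([(10.0, 0, "front", 1, 1, 10.0),
                          (0.0, 0, "front", 1, 1, 10.0)])
        with pytest.raises(ValueError):
            ev.group_coincidences(hits)

    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_partition_and_greedy_rule(self, times):
        times = sorted(times)
        hits = make_hits([(t, 0, "front", 1, 1, 10.0) for t in times])
        out = ev.group_coincidences(hits, 100.0)
        eid = out["event_id"].to_numpy()
        # every hit in exactly one event, ids contiguous from 0
        assert len(eid) == len(times)
        assert set(np.unique(eid)) == set(range(eid.max() + 1))
        # greedy reference implementation
        ref = []
        current = -1
        opener_t = -np.inf
        for t in times:
            if t - opener_t > 100.0:
                current += 1
                opener_t = t
            ref.append(current)
        assert eid.tolist() == ref

    def test_energy_conserved_by_grouping(self):
        rngv = np.random.default_rng(5)
        times = np.sort(rngv.uniform(0, 1e5, size=200))
        e = rngv.uniform(10, 700, size=200)
        hits = make_hits([(t, 0, "rear", 1, 1, x) for t, x in zip(times, e)])
        out = ev.group_coincidences(hits)
        assert out.groupby("event_id")["energy_kev"].sum().sum() == pytest.approx(e.sum())


class TestClassification:
    def test_front_and_rear_is_compton_candidate(self):
        hits = ev.group_coincidences(make_hits(
            [(0.0, 0, "front", 3, 3, 150.0), (1.0, 0, "rear", 4, 4, 512.0)]))
        event = ev.Event(hits)
        assert ev.classify_event(event, "compton") == [0]
        assert ev.classify_event(event, "pinhole") == []

    def test_rear_only_is_pinhole_candidate(self):
        hits = ev.group_coincidences(make_hits([(0.0, 2, "rear", 4, 4, 60.0)]))
        event = ev.Event(hits)
        assert ev.classify_event(event, "pinhole") == [2]
        assert ev.classify_event(event, "compton") == []

    def test_two_cameras_form_pet_candidate(self):
        hits = ev.group_coincidences(make_hits(
            [(0.0, 0, "rear", 4, 4, 511.0), (1.0, 2, "rear", 9, 9, 511.0)]))
        event = ev.Event(hits)
        assert ev.classify_event(event, "pet") == [(0, 2)]

    def test_unknown_mode_raises(self):
        hits = ev.group_coincidences(make_hits([(0.0, 0, "rear", 4, 4, 60.0)]))
        with pytest.raises(ValueError):
            ev.classify_event(ev.Event(hits), "spect")


class TestEnergyCuts:
    def test_cs137_event_inside_both_windows_kept(self):
        cand = pd.DataFrame({"E_f": [50.0], "E_r": [600.0]})
        assert len(ev.apply_energy_cut(cand, "cs137")) == 1

    def test_cs137_back_scatter_rejected_by_front_window(self):
        cand = pd.DataFrame({"E_f": [150.0], "E_r": [512.0]})
        assert len(ev.apply_energy_cut(cand, "cs137")) == 0

    def test_am241_rear_window(self):
        cand = pd.DataFrame({"E_f": [0.0], "E_r": [60.0]})
        assert len(ev.apply_energy_cut(cand, "am241")) == 1

    def test_unknown_target_raises(self):
        with pytest.raises(ValueError):
            ev.apply_energy_cut(pd.DataFrame({"E_f": [1.0], "E_r": [1.0]}), "tc99m")

    def test_explicit_windows_accepted(self):
        cand = pd.DataFrame({"E_f": [0.0], "E_r": [140.0]})
        win = (ev.EnergyWindow(120, 160, "E_r"),)
        assert len(ev.apply_energy_cut(cand, win)) == 1


class TestScatterAngle:
    def test_forward_limit_zero_angle(self):
        assert ev.compute_scatter_angle(1e-9, 662.0) == pytest.approx(0.0, abs=1e-3)

    def test_known_pair_thirty_degrees(self):
        theta = ev.compute_scatter_angle(100.0, 562.0)
        assert np.degrees(theta) == pytest.approx(30.4, abs=0.1)

    def test_kinematically_invalid_pair_flagged(self):
        assert np.isnan(ev.compute_scatter_angle(400.0, 100.0))

    def test_nonpositive_energy_raises(self):
        with pytest.raises(ValueError):
            ev.compute_scatter_angle(0.0, 300.0)

    def test_round_trip_with_sampled_kinematics(self, rng):
        # full absorption: the energy pair must reproduce the sampled angle
        theta, e_sc = sim.sample_klein_nishina(np.full(200, 662.0), rng)
        rec = ev.compute_scatter_angle(662.0 - e_sc, e_sc)
        assert np.allclose(rec, theta, atol=1e-9)


class TestBulkSelection:
    def test_compton_selection_matches_manual_rules(self, poses):
        hits = make_hits([
            (0.0, 0, "front", 10, 22, 50.0), (1.0, 0, "rear", 22, 22, 600.0),
            (1000.0, 0, "front", 10, 22, 150.0), (1001.0, 0, "rear", 22, 22, 512.0),
            (2000.0, 1, "rear", 5, 5, 60.0),
        ])
        grouped = ev.group_coincidences(hits)
        sel = ev.select_compton(grouped, poses, "cs137")
        assert len(sel) == 1
        assert sel.loc[0, "E_f"] == 50.0
        # scatter position is the front pixel center in world coordinates
        expected = poses[0][0].pixel_center_world("front", 10, 22)
        assert np.allclose(
            sel.loc[0, ["scatter_x", "scatter_y", "scatter_z"]].astype(float), expected
        )

    def test_multi_hit_plane_takes_highest_energy_pixel(self, poses):
        hits = make_hits([
            (0.0, 0, "front", 10, 22, 20.0), (0.5, 0, "front", 12, 22, 40.0),
            (1.0, 0, "rear", 22, 22, 600.0),
        ])
        sel = ev.select_compton(ev.group_coincidences(hits), poses, "cs137")
        assert len(sel) == 1
        assert sel.loc[0, "E_f"] == 60.0  # summed per plane
        expected = poses[0][0].pixel_center_world("front", 12, 22)
        assert np.allclose(
            sel.loc[0, ["scatter_x", "scatter_y", "scatter_z"]].astype(float), expected
        )

    def test_pinhole_selection_excludes_front_hits(self):
        hits = make_hits([
            (0.0, 1, "rear", 4, 4, 60.0),
            (1000.0, 1, "front", 3, 3, 30.0), (1001.0, 1, "rear", 4, 4, 60.0),
        ])
        sel = ev.select_pinhole(ev.group_coincidences(hits), "am241")
        assert len(sel) == 1 and sel.loc[0, "E_r"] == 60.0

    def test_pet_pairing_and_ambiguity(self, poses):
        hits = make_hits([
            (0.0, 0, "rear", 22, 22, 511.0), (1.0, 2, "rear", 22, 22, 511.0),
            (1e4, 0, "rear", 22, 22, 511.0), (1e4 + 1, 1, "rear", 22, 22, 400.0),
            (2e4, 0, "rear", 22, 22, 500.0), (2e4 + 1, 1, "rear", 22, 22, 520.0),
            (2e4 + 2, 2, "rear", 22, 22, 480.0),
        ])
        pairs = ev.select_pet(ev.group_coincidences(hits), poses, "na22")
        # first event pairs, second misses the window, third is ambiguous
        assert len(pairs) == 1
        assert np.allclose(pairs.loc[0, ["az"]], 190.0) or np.allclose(pairs.loc[0, ["az"]], -190.0)


def test_event_partition_total_energy(ring, poses):
    """Simulated hits: selection never duplicates or loses deposits."""
    src = sim.SourceSpec("cs137", activity_bq=1e5, position=(0, 0, 0))
    res = sim.simulate_acquisition(src, ring, duration_s=2.0, seed=3)
    grouped = ev.group_by_angle(res.hits)
    # partition: event ids within an angle are contiguous; energy conserved
    assert grouped["energy_kev"].sum() == pytest.approx(res.hits["energy_kev"].sum())
    assert len(grouped) == len(res.hits)
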
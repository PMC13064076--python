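"""MTED: segmentation, the four event features, containment, oracle parity."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from astroca.events import (
    DEFAULT_LADDER,
    CaEvent,
    EventTable,
    ThresholdLadder,
    detect_events,
    event_features,
    threshold_profile,
)
from astroca.pipeline import process_recording
from astroca.ratiometric import DffMovie
from astroca.scenarios import small_scene

from helpers import flood_fill_components


def _dff(arr, pixel_size=1.0, frame_interval=0.2):
    arr = np.asarray(arr, dtype=np.float32)
    return DffMovie(
        dff=arr,
        mask=np.ones(arr.shape[1:], bool),
        pixel_size=pixel_size,
        frame_interval=frame_interval,
    )


def test_ladder_must_increase():
    with pytest.raises(ValueError):
        ThresholdLadder((2.0, 1.0))
    with pytest.raises(ValueError):
        ThresholdLadder(())


def test_silent_movie_yields_no_events():
    table = detect_events(_dff(np.zeros((20, 16, 16))))
    assert len(table.events) == 0


def test_two_pulses_same_footprint_are_two_events():
    arr = np.zeros((30, 16, 16))
    arr[5:10, 4:8, 4:8] = 3.0
    arr[20:25, 4:8, 4:8] = 3.0
    table = detect_events(_dff(arr), ThresholdLadder((2.0,)))
    assert len(table.at_level(2.0)) == 2


def test_subthreshold_events_absent_at_higher_levels():
    arr = np.zeros((20, 16, 16))
    arr[5:10, 4:8, 4:8] = 1.5
    table = detect_events(_dff(arr))
    profile = threshold_profile(table)
    assert profile.loc[profile.threshold >= 2.0, "n_events"].sum() == 0
    assert len(table.at_level(1.0)) == 1


def test_noise_filters_reject_specks():
    arr = np.zeros((20, 16, 16))
    arr[5, 4, 4] = 10.0  # single voxel
    arr[10:12, 8, 8] = 10.0  # 1 px for 2 frames, below min_area
    assert len(detect_events(_dff(arr), ThresholdLadder((2.0,))).events) == 0


def test_invalid_connectivity_rejected():
    with pytest.raises(ValueError):
        detect_events(_dff(np.zeros((5, 4, 4))), connectivity=4)


class TestEventFeatures:
    def test_static_square(self):
        comp = np.zeros((20, 32, 32), bool)
        comp[:, 10:20, 10:20] = True
        dff = np.where(comp, 3.0, 0.0)
        ev = event_features(comp, dff, 1.0, 0.2, threshold=2.0)
        assert ev.max_size == 100.0
        assert ev.duration == pytest.approx(4.0)
        assert ev.distance == 0.0

    def test_moving_centroid_distance(self):
        # centroid translating 1 px/frame for 11 frames -> 10 um displacement
        comp = np.zeros((11, 8, 24), bool)
        for f in range(11):
            comp[f, 2:5, 2 + f : 5 + f] = True
        dff = np.where(comp, 2.5, 0.0)
        ev = event_features(comp, dff, 1.0, 0.2, threshold=2.0)
        assert ev.distance == pytest.approx(10.0, abs=1e-9)

    def test_linear_ramp_slope(self):
        # dff 0 -> 2 in uniform steps of 0.2 per frame at 5 fps -> 1.0 1/s
        comp = np.zeros((11, 6, 6), bool)
        comp[:, 2:4, 2:4] = True
        dff = np.zeros((11, 6, 6))
        for f in range(11):
            dff[f, 2:4, 2:4] = 0.2 * f
        ev = event_features(comp, dff, 1.0, 0.2, threshold=0.1)
        assert ev.max_slope == pytest.approx(1.0, rel=1e-9)

    def test_single_frame_component_flagged(self):
        comp = np.zeros((5, 6, 6), bool)
        comp[2, 2:4, 2:4] = True
        ev = event_features(comp, np.full((5, 6, 6), 3.0), 1.0, 0.2, threshold=2.0)
        assert ev.single_frame and ev.max_slope == 0.0

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            event_features(np.zeros((3, 4, 4), bool), np.zeros((3, 4, 4)), 1, 0.2, 2)


class TestPlantedRecovery:
    def test_features_match_ground_truth_at_threshold_two(self, small_run):
        movie, geom, gt, hill, res = small_run
        table = detect_events(res.dff, ThresholdLadder((2.0,)), n_cells=1)
        det = table.to_dataframe().sort_values("first_frame").reset_index(drop=True)
        tru = gt.true_features.sort_values("onset_frame").reset_index(drop=True)
        assert len(det) == len(tru) == 3
        assert np.array_equal(det.first_frame, tru.onset_frame)
        assert np.array_equal(det.last_frame, tru.offset_frame)
        assert np.allclose(det.max_size, tru.max_size)  # exact
        assert np.allclose(det.duration, tru.duration)  # exact
        assert np.allclose(det.distance, tru.distance, atol=1.0)  # <= 1 px
        assert np.allclose(det.max_slope, tru.max_slope, rtol=1e-3)

    def test_counts_non_increasing_across_ladder(self):
        for seed in range(5):
            movie, geom, gt, hill = small_scene(seed=seed)
            res = process_recording(movie, None, hill, f0_window=40)
            table = detect_events(res.dff, n_cells=1)
            counts = [len(table.at_level(lv)) for lv in DEFAULT_LADDER]
            assert all(b <= a for a, b in zip(counts, counts[1:])), (seed, counts)

    def test_higher_threshold_voxels_nested_in_lower(self, small_run):
        *_, res = small_run
        filled = np.where(res.dff.mask[None], res.dff.dff, -np.inf)
        lab_low, _ = ndi.label(filled >= 2.0, structure=np.ones((3, 3, 3)))
        assert np.all(lab_low[filled >= 5.0] > 0)


@pytest.mark.parametrize("connectivity", [6, 26])
def test_labeling_agrees_with_bruteforce_flood_fill(small_run, connectivity):
    *_, res = small_run
    crop = np.nan_to_num(res.dff.dff[:50, :32, :32], nan=-1.0) >= 2.0
    structure = (
        ndi.generate_binary_structure(3, 1)
        if connectivity == 6
        else np.ones((3, 3, 3), bool)
    )
    labels, n = ndi.label(crop, structure=structure)
    ours = {frozenset(zip(*np.nonzero(labels == i))) for i in range(1, n + 1)}
    ref = set(flood_fill_components(crop, connectivity))
    assert ours == ref


def test_per_cell_frequency_halves_when_cells_double(small_run):
    *_, res = small_run
    t1 = detect_events(res.dff, ThresholdLadder((2.0,)), n_cells=1)
    t2 = detect_events(res.dff, ThresholdLadder((2.0,)), n_cells=2)
    p1 = threshold_profile(t1, ThresholdLadder((2.0,)))
    p2 = threshold_profile(t2, ThresholdLadder((2.0,)))
    assert p2.events_per_cell[0] == p1.events_per_cell[0] / 2


def test_event_table_validates_frame_span():
    ev = CaEvent(0, 2.0, 0, 99, 10.0, 1.0, 0.0, 0.1, 50)
    with pytest.raises(ValueError):
        EventTable(
            recording_id="r", condition="Ctrl", n_cells=1, duration_recorded=10.0,
            pixel_size=1.0, frame_interval=0.2, n_frames=50, events=[ev],
        )
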
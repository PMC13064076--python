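"""Generator contracts: geometry, kinetics, rendering, ground-truth oracle."""

import numpy as np
import pytest

from astroca.hill import HillParams, brightness, hill_saturation
from astroca.ratiometric import MixingMatrix
from astroca.scenarios import small_scene
from astroca.synthetic import (
    NoiseModel,
    PlantedEvent,
    make_cell_geometry,
    render_fluorescence,
    simulate_calcium,
    square_event,
)

from helpers import features_from_concentration

HILL = HillParams(dyn_range=8.0)


class TestGeometry:
    def test_single_cell_anchor(self):
        geom = make_cell_geometry(1, fov=(64, 64), seed=7)
        assert geom.n_cells == 1
        assert geom.vf.max() == 1.0
        cy, cx = geom.soma_centers[0].astype(int)
        assert geom.vf[cy, cx] == 1.0

    def test_deterministic_for_fixed_seed(self):
        a = make_cell_geometry(2, fov=(96, 96), seed=7)
        b = make_cell_geometry(2, fov=(96, 96), seed=7)
        assert np.array_equal(a.vf, b.vf)
        assert np.array_equal(a.cell_labels, b.cell_labels)

    def test_peripheral_band_is_populated(self):
        # process tips must reach below the 12.5 % volume-fraction band
        geom = make_cell_geometry(3, fov=(256, 256), seed=1)
        cell_vf = geom.vf[geom.cell_labels > 0]
        assert (cell_vf <= 0.125).any()

    def test_background_is_exactly_empty(self):
        geom = make_cell_geometry(2, fov=(96, 96), seed=3)
        assert np.all((geom.vf == 0) == (geom.cell_labels == 0))

    def test_placement_error_when_fov_too_small(self):
        with pytest.raises(ValueError):
            make_cell_geometry(30, fov=(48, 48), seed=0)


class TestSimulateCalcium:
    def test_no_events_gives_uniform_basal(self):
        geom = make_cell_geometry(1, fov=(48, 48), seed=0, soma_radius=5.0)
        ca, gt = simulate_calcium(geom, [], HILL, 20, 0.2)
        assert np.all(ca == HILL.basal_ca)
        assert len(gt.true_features) == 0

    def test_square_event_arithmetic(self):
        # 10x10 px at 1 um/px for 20 frames at 0.2 s -> 100 um^2, 4 s
        fp = np.array([(r, c) for r in range(10) for c in range(10)]) + 20
        ev = PlantedEvent(
            cell_id=1, onset_frame=5, offset_frame=24, peak_ca=500.0,
            footprints=[fp] * 20,
        )
        geom = make_cell_geometry(1, fov=(64, 64), seed=0, soma_radius=18.0)
        # recenter footprint on the soma so it lies inside the cell
        cy, cx = geom.soma_centers[0].astype(int)
        ev.footprints = [fp - 24 + np.array([cy, cx])] * 20
        ca, gt = simulate_calcium(geom, [ev], HILL, 40, 0.2)
        row = gt.true_features.iloc[0]
        assert row.max_size == 100.0
        assert row.duration == pytest.approx(4.0)
        assert row.distance == 0.0

    def test_footprint_outside_cell_rejected(self):
        geom = make_cell_geometry(1, fov=(48, 48), seed=0, soma_radius=4.0)
        ev = square_event(1, (2, 2), 1, 0, 5, 400.0)  # corner, not in the cell
        with pytest.raises(ValueError, match="cell mask|field of view"):
            simulate_calcium(geom, [ev], HILL, 10, 0.2)

    def test_ground_truth_matches_bruteforce_from_movie(self):
        movie, geom, gt, hill = small_scene(seed=2)
        ca, _ = simulate_calcium(
            geom, gt.events, hill, n_frames=80, frame_interval=0.2
        )
        for eid, ev in enumerate(gt.events):
            ref = features_from_concentration(ca, ev, hill, geom.pixel_size, 0.2)
            row = gt.true_features.iloc[eid]
            for key, val in ref.items():
                assert row[key] == pytest.approx(val, rel=1e-9), key


class TestRender:
    @pytest.fixture()
    def geom(self):
        return make_cell_geometry(1, fov=(48, 48), seed=4, soma_radius=5.0)

    def test_zero_calcium_ratio_uniform(self, geom):
        ca = np.zeros((5,) + geom.vf.shape)
        m = render_fluorescence(ca, geom, HILL)
        cells = geom.cell_labels > 0
        ratio = m.green[0][cells] / m.red[0][cells]
        assert np.allclose(ratio, 1.0, atol=1e-6)

    def test_half_saturation_ratio(self, geom):
        ca = np.full((3,) + geom.vf.shape, HILL.kd)
        m = render_fluorescence(ca, geom, HILL, red_coeff=2.0)
        cells = geom.cell_labels > 0
        expected = (1 + (HILL.dyn_range - 1) * 0.5) / 2.0
        assert np.allclose(m.green[0][cells] / m.red[0][cells], expected, rtol=1e-6)

    def test_resting_brightness_uses_hill_saturation(self, geom):
        hill = HillParams()  # default dyn_range 50
        ca = np.full((2,) + geom.vf.shape, 50.0)
        m = render_fluorescence(ca, geom, hill)
        cells = geom.cell_labels > 0
        theta = hill_saturation(50.0, hill)
        assert theta == pytest.approx(0.0697, abs=5e-4)
        assert np.allclose(
            m.green[0][cells] / m.red[0][cells], 1 + 49 * theta, rtol=1e-5
        )

    def test_red_channel_time_invariant(self):
        movie, *_ = small_scene(seed=1)
        assert np.array_equal(movie.red[0], movie.red[-1])

    def test_green_peak_monotone_in_peak_ca(self, geom):
        cy, cx = geom.soma_centers[0].astype(int)
        peaks = []
        for peak_ca in (200.0, 400.0, 800.0):
            ev = square_event(1, (cy, cx), 1, 2, 6, peak_ca)
            ca, _ = simulate_calcium(geom, [ev], HILL, 12, 0.2)
            m = render_fluorescence(ca, geom, HILL)
            peaks.append(m.green[:, cy, cx].max())
        assert peaks[0] < peaks[1] < peaks[2]

    def test_noiseless_render_deterministic_and_noise_seeded(self, geom):
        ca = np.full((4,) + geom.vf.shape, 100.0)
        ca[:, geom.cell_labels == 0] = 0.0
        a = render_fluorescence(ca, geom, HILL, seed=1)
        b = render_fluorescence(ca, geom, HILL, seed=2)
        assert np.array_equal(a.green, b.green)
        noise = NoiseModel(photons_per_unit=0.5, read_sigma=1.0)
        n1 = render_fluorescence(ca, geom, HILL, noise=noise, seed=3)
        n2 = render_fluorescence(ca, geom, HILL, noise=noise, seed=3)
        assert np.array_equal(n1.green, n2.green)
        assert not np.array_equal(n1.green, a.green)

    def test_crosstalk_mixes_channels(self, geom):
        ca = np.zeros((2,) + geom.vf.shape)
        mix = MixingMatrix(np.array([[1.0, 0.5], [0.0, 1.0]]))
        pure = render_fluorescence(ca, geom, HILL)
        mixed = render_fluorescence(ca, geom, HILL, crosstalk=mix)
        assert np.allclose(mixed.green, pure.green + 0.5 * pure.red, rtol=1e-6)
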
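"""Normalization chain: unmixing, F0 baselines, scale factor, dF/F_R."""

import numpy as np
import pytest
from scipy import stats

from astroca.hill import HillParams, brightness, dff_of_ca
from astroca.ratiometric import (
    BaselineMap,
    MixingMatrix,
    ReferenceMap,
    TwoChannelMovie,
    compute_dff,
    compute_scale_factor,
    estimate_f0,
    make_reference,
    unmix,
)
from astroca.scenarios import DEFAULT_CROSSTALK, basal_movie, small_scene
from astroca.synthetic import make_cell_geometry, render_fluorescence, simulate_calcium

from helpers import brute_percentile_envelope


def _movie(green, red):
    return TwoChannelMovie(green=green, red=red, pixel_size=1.0, frame_interval=0.2)


class TestUnmix:
    def test_identity_mixing_is_noop(self):
        rng = np.random.default_rng(0)
        m = _movie(rng.random((4, 8, 8)), rng.random((4, 8, 8)))
        out = unmix(m, MixingMatrix())
        assert np.allclose(out.green, m.green, atol=1e-7)
        assert np.allclose(out.red, m.red, atol=1e-7)

    def test_crosstalk_roundtrip_recovers_pure_channels(self):
        movie, geom, gt, hill = small_scene(seed=3)
        mixed_green = (
            DEFAULT_CROSSTALK.matrix[0, 0] * movie.green
            + DEFAULT_CROSSTALK.matrix[0, 1] * movie.red
        )
        mixed_red = (
            DEFAULT_CROSSTALK.matrix[1, 0] * movie.green
            + DEFAULT_CROSSTALK.matrix[1, 1] * movie.red
        )
        rec = unmix(_movie(mixed_green, mixed_red), DEFAULT_CROSSTALK)
        scale = movie.green.max()
        assert np.allclose(rec.green, movie.green, atol=1e-6 * scale)
        assert np.allclose(rec.red, movie.red, atol=1e-6 * scale)

    def test_singular_matrix_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            MixingMatrix(np.ones((2, 2)))


class TestEstimateF0:
    def test_constant_trace_returns_constant(self):
        stack = np.full((120, 4, 4), 100.0)
        f0 = estimate_f0(stack, window=50, percentile=8)
        assert np.allclose(f0.f0, 100.0)

    def test_step_trace_takes_low_plateau(self):
        # 100 for frames 0-99 then 300 for 100-199; window 50, 10th pct
        trace = np.concatenate([np.full(100, 100.0), np.full(100, 300.0)])
        stack = trace[:, None, None]
        f0 = estimate_f0(stack, window=50, percentile=10, smooth=0)
        assert f0.f0[0, 0] == brute_percentile_envelope(trace, 50, 10) == 100.0

    def test_matches_bruteforce_on_noisy_trace(self):
        rng = np.random.default_rng(1)
        trace = 50 + rng.random(150) * 20
        f0 = estimate_f0(trace[:, None, None], window=40, percentile=8, smooth=0)
        assert f0.f0[0, 0] == pytest.approx(
            brute_percentile_envelope(trace, 40, 8), rel=1e-6
        )

    def test_recovers_rendered_basal_brightness(self, small_run):
        movie, geom, gt, hill, res = small_run
        cells = geom.cell_labels > 0
        expected = 100.0 * geom.vf[cells] * brightness(hill.basal_ca, hill)
        assert np.allclose(res.f0_green.f0[cells], expected, rtol=0.01)

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ValueError):
            estimate_f0(np.zeros((10, 2, 2)), window=11)

    def test_percentile_range_enforced(self):
        with pytest.raises(ValueError):
            estimate_f0(np.zeros((10, 2, 2)), window=5, percentile=60)


class TestScaleFactor:
    def test_closed_form_with_unequal_channel_gains(self):
        # red_coeff c makes the true factor 1/c, independent of basal_ca
        hill = HillParams(dyn_range=8.0)
        geom = make_cell_geometry(1, fov=(48, 48), seed=5, soma_radius=5.0)
        ca, _ = simulate_calcium(geom, [], hill, 30, 0.2)
        m = render_fluorescence(ca, geom, hill, red_coeff=2.0)
        f0g = estimate_f0(m.green, window=20)
        f0r = estimate_f0(m.red, window=20)
        k = compute_scale_factor(f0g, f0r, hill, geom.cell_labels > 0)
        assert k == pytest.approx(0.5, rel=1e-6)

    def test_zero_basal_divisor_is_unity(self):
        hill = HillParams(basal_ca=0.0)
        f0g = BaselineMap(np.full((4, 4), 30.0), 10, 8)
        f0r = BaselineMap(np.full((4, 4), 10.0), 10, 8)
        k = compute_scale_factor(f0g, f0r, hill, np.ones((4, 4), bool))
        assert k == pytest.approx(3.0)

    def test_empty_mask_rejected(self):
        f0 = BaselineMap(np.ones((4, 4)), 10, 8)
        with pytest.raises(ValueError):
            compute_scale_factor(f0, f0, HillParams(), np.zeros((4, 4), bool))


class TestComputeDff:
    def test_equal_signal_and_reference_is_zero(self):
        fr = np.full((4, 4), 10.0)
        ref = ReferenceMap(fr=fr, scale_k=1.0)
        m = _movie(np.broadcast_to(fr, (3, 4, 4)).copy(), np.ones((3, 4, 4)))
        dff = compute_dff(m, ref)
        assert np.allclose(dff.dff, 0.0)

    def test_triple_signal_gives_two(self):
        fr = np.full((4, 4), 10.0)
        ref = ReferenceMap(fr=fr, scale_k=1.0)
        m = _movie(np.broadcast_to(3 * fr, (3, 4, 4)).copy(), np.ones((3, 4, 4)))
        assert np.allclose(compute_dff(m, ref).dff, 2.0)

    def test_dff_never_below_minus_one(self, small_run):
        *_, res = small_run
        d = res.dff.dff[:, res.dff.mask]
        assert np.all(d >= -1.0)

    def test_peak_dff_matches_hill_closed_form(self, small_run):
        movie, geom, gt, hill, res = small_run
        for _, row in gt.true_features.iterrows():
            ev = gt.events[int(row.event_id)]
            fp = ev.footprints[ev.rise_frames - 1]
            peak_frame = ev.onset_frame + ev.rise_frames - 1
            measured = res.dff.dff[peak_frame][fp[:, 0], fp[:, 1]].mean()
            assert measured == pytest.approx(dff_of_ca(ev.peak_ca, hill), rel=0.01)


def test_reference_tracks_true_volume_fraction(small_run):
    # F0(red) must rank-order the simulated per-pixel volume exactly
    movie, geom, gt, hill, res = small_run
    cells = geom.cell_labels > 0
    rho = stats.spearmanr(res.f0_red.f0[cells], geom.vf[cells]).statistic
    assert rho >= 0.99


def test_make_reference_requires_positive_scale():
    with pytest.raises(ValueError):
        make_reference(BaselineMap(np.ones((2, 2)), 5, 8), scale_k=0.0)
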
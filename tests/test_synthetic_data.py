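"""Generator ground truth: construction invariants and determinism."""

import numpy as np
import pytest

from sphenostim.io_core import TimeSeries
from sphenostim.synthetic_data import (
    BolusSpec,
    EcogEvent,
    EcogSpec,
    StackGeometry,
    VesselSpec,
    make_angio_stack,
    make_coronal_sections,
    make_ecog,
    make_evansblue_image,
    make_vessel_stack,
)
from conftest import ANGIO_GEOMETRY, rect_roi


class TestVesselStack:
    def test_noiseless_run_length_is_20px(self, horizontal_vessel):
        """A 20-um vessel at 1 um/px renders 20 px of foreground per column."""
        stack, _ = horizontal_vessel
        frame = stack.frames[0]
        fg = frame > (frame.min() + frame.max()) / 2
        run_lengths = fg[:, 20:80].sum(axis=0)
        assert (run_lengths == 20).all()

    def test_ramp_truth_ratio(self):
        geom = StackGeometry(n_frames=10)
        d = 20.0 * (1.0 + 0.12 * np.arange(10) / 9)
        spec = VesselSpec(centerline=[(48.5, 8.0), (48.5, 88.0)], diameter_um=d)
        _, truth = make_vessel_stack(spec, geom, seed=0)
        first = truth[truth.frame == 0].diam_um.mean()
        last = truth[truth.frame == 9].diam_um.mean()
        assert last / first == pytest.approx(1.12)

    def test_same_seed_bitwise_identical(self):
        spec = VesselSpec(centerline=[(48.5, 8.0), (48.5, 88.0)], noise_sd=5.0)
        s1, t1 = make_vessel_stack(spec, StackGeometry(n_frames=4), seed=11)
        s2, t2 = make_vessel_stack(spec, StackGeometry(n_frames=4), seed=11)
        np.testing.assert_array_equal(s1.frames, s2.frames)
        assert t1.equals(t2)

    def test_vessel_wider_than_image_rejected(self):
        spec = VesselSpec(centerline=[(48.5, 8.0), (48.5, 88.0)], diameter_um=200.0)
        with pytest.raises(ValueError, match="wider"):
            make_vessel_stack(spec, StackGeometry(), seed=0)


class TestAngioStack:
    def test_programmed_p2p_interval(self, bolus_pair):
        _, _, truth = bolus_pair
        assert truth["p2p_interval_s"] == pytest.approx(1.5)

    def test_linear_ramp_slope_truth(self):
        spec = BolusSpec(roi=rect_roi("artery", 10, 10), arrival_s=1.0,
                         rise_tau_s=2.0, peak_iu=110.0, baseline_iu=10.0)
        assert spec.slope_iu_per_s == pytest.approx(50.0)
        t = np.array([0.5, 1.0, 2.0, 3.0])
        np.testing.assert_allclose(spec.curve(t)[:3], [10.0, 10.0, 60.0])

    def test_overlapping_rois_rejected(self):
        a = BolusSpec(roi=rect_roi("artery", 10, 10), arrival_s=1.0, rise_tau_s=1.0, peak_iu=50.0)
        b = BolusSpec(roi=rect_roi("vein", 15, 15), arrival_s=2.0, rise_tau_s=1.0, peak_iu=50.0)
        with pytest.raises(ValueError, match="overlap"):
            make_angio_stack([a, b], ANGIO_GEOMETRY, seed=0)

    def test_noisy_roi_mean_tracks_programmed_curve(self):
        """Monte-Carlo: empirical ROI mean within 3 SE of the programmed curve."""
        spec = BolusSpec(roi=rect_roi("artery", 10, 10), arrival_s=1.0,
                         rise_tau_s=1.0, peak_iu=110.0, baseline_iu=10.0)
        geom = StackGeometry(frame_interval_s=1.0 / 30.0, n_frames=120)
        n_rep, n_px = 100, 100
        t = np.arange(geom.n_frames) * geom.frame_interval_s
        expected = spec.curve(t)
        mask = spec.roi.to_mask(geom.shape)
        means = np.empty((n_rep, geom.n_frames))
        for k in range(n_rep):
            stack, _ = make_angio_stack([spec], geom, seed=k, noise_sd=5.0)
            means[k] = stack.frames[:, mask].mean(axis=1)
        se = 5.0 / np.sqrt(n_px * n_rep)
        assert np.all(np.abs(means.mean(axis=0) - expected) < 3 * se)


class TestEcog:
    def test_no_events_gives_empty_truth(self):
        _, truth = make_ecog(EcogSpec(duration_s=60.0), seed=0)
        assert truth.empty

    def test_event_truth_records_programmed_duration(self):
        ev = EcogEvent(onset_s=10.0, duration_s=4.0, amplitude_multiple=5.0)
        _, truth = make_ecog(EcogSpec(duration_s=60.0, events=[ev]), seed=0)
        assert len(truth) == 1
        assert truth.duration_s.iloc[0] == 4.0
        assert 71.0 <= truth.carrier_hz.iloc[0] <= 90.0

    def test_background_sd_matches_spec_rms(self):
        """Spectral synthesis puts the programmed RMS into the 2-90 Hz band."""
        ts, _ = make_ecog(EcogSpec(duration_s=120.0, rms_uv=50.0), seed=4)
        assert np.std(ts.values) == pytest.approx(50.0, rel=0.05)

    def test_event_outside_recording_rejected(self):
        ev = EcogEvent(onset_s=58.0, duration_s=4.0)
        with pytest.raises(ValueError, match="fit"):
            EcogSpec(duration_s=60.0, events=[ev])

    def test_same_seed_identical(self):
        a, _ = make_ecog(EcogSpec(duration_s=30.0), seed=9)
        b, _ = make_ecog(EcogSpec(duration_s=30.0), seed=9)
        np.testing.assert_array_equal(a.values, b.values)


class TestEvansBlue:
    def test_zero_fraction_hemispheres_identical(self):
        img, masks, _ = make_evansblue_image(0.0, seed=0)
        blue = img[..., 2].astype(float)
        assert blue[masks["treated"]].mean() == blue[masks["control"]].mean()

    def test_quarter_fraction_exact_noiseless(self):
        img, masks, truth = make_evansblue_image(0.25, intensity_level=180,
                                                 background_blue=60, seed=0)
        blue = img[..., 2]
        frac = np.mean(blue[masks["treated"]] > 120)
        assert frac == pytest.approx(0.25, abs=1e-3)
        assert truth["mean_blue_in_blob"] == 180.0

    def test_blob_mean_matches_programmed_level(self):
        img, masks, _ = make_evansblue_image(0.25, intensity_level=180, seed=0)
        assert img[..., 2][masks["blob"]].mean() == 180.0


class TestCoronalSections:
    def test_zero_loss_equal_pixel_counts(self):
        sections, truth = make_coronal_sections(n_sections=4, loss_fraction=0.0, seed=0)
        for _, ipsi, contra in sections:
            assert ipsi.sum() == contra.sum()
        assert truth["aggregate_pct_loss"] == 0.0

    def test_uniform_loss_aggregate(self):
        _, truth = make_coronal_sections(n_sections=6, loss_fraction=0.371, seed=0)
        assert truth["aggregate_pct_loss"] == pytest.approx(37.1, abs=0.1)

    def test_section_count(self):
        sections, _ = make_coronal_sections(n_sections=6, loss_fraction=0.2, seed=0)
        assert len(sections) == 6
        img, ipsi, contra = sections[0]
        assert img.shape[:2] == ipsi.shape == contra.shape
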
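"""Bolus-transit metrics: peak recovery, slope oracle, invariances."""

import numpy as np
import pytest

from sphenostim.angiography_kinetics import (
    peak_to_peak,
    roi_intensity_curve,
    slope_to_max,
    transit_metrics,
)
from sphenostim.io_core import ImageStack, ROI
from sphenostim.synthetic_data import BolusSpec, StackGeometry, make_angio_stack
from conftest import ANGIO_GEOMETRY, rect_roi

FRAME = 1.0 / 30.0


class TestRoiIntensityCurve:
    def test_peak_time_recovery(self, bolus_pair):
        stack, (art, _), truth = bolus_pair
        trace = roi_intensity_curve(stack, art.roi)
        assert trace.peak_time_s == pytest.approx(truth["peak_time_s"]["artery"], abs=FRAME)

    def test_constant_stack_flags_no_bolus(self):
        stack = ImageStack(np.full((30, 32, 32), 42.0), 1.0, FRAME)
        roi = rect_roi("artery", 5, 5, shape=(32, 32))
        with pytest.warns(UserWarning, match="no bolus"):
            trace = roi_intensity_curve(stack, roi)
        assert not trace.bolus_detected
        assert trace.peak_iu == pytest.approx(trace.baseline_iu)

    def test_single_pixel_roi_equals_pixel_course(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(0, 100, size=(40, 16, 16))
        stack = ImageStack(frames, 1.0, FRAME)
        mask = np.zeros((16, 16), dtype=bool)
        mask[7, 7] = True
        trace = roi_intensity_curve(stack, ROI(label="other", mask=mask))
        np.testing.assert_allclose(trace.series.values, frames[:, 7, 7])


class TestPeakToPeak:
    def test_programmed_interval_recovered(self, bolus_pair):
        stack, (art, ven), truth = bolus_pair
        ta = roi_intensity_curve(stack, art.roi)
        tv = roi_intensity_curve(stack, ven.roi)
        assert peak_to_peak(ta, tv) == pytest.approx(truth["p2p_interval_s"], abs=FRAME)

    def test_identical_traces_give_zero(self, bolus_pair):
        stack, (art, _), _ = bolus_pair
        ta = roi_intensity_curve(stack, art.roi)
        assert peak_to_peak(ta, ta) == 0.0

    def test_missing_peak_names_roi(self):
        stack = ImageStack(np.full((30, 32, 32), 42.0), 1.0, FRAME)
        roi = rect_roi("vein", 5, 5, shape=(32, 32))
        with pytest.warns(UserWarning):
            trace = roi_intensity_curve(stack, roi)
        with pytest.raises(ValueError, match="vein"):
            peak_to_peak(trace, trace)

    def test_monotone_decreasing_p2p_over_flow_series(self):
        """Faster programmed transit gives strictly decreasing p2p estimates."""
        estimates = []
        for k, delay in enumerate([1.5, 1.2, 0.9, 0.6, 0.3]):
            art = BolusSpec(roi=rect_roi("artery", 10, 10), arrival_s=1.0,
                            rise_tau_s=1.0, peak_iu=110.0)
            ven = BolusSpec(roi=rect_roi("vein", 50, 50), arrival_s=1.0 + delay,
                            rise_tau_s=1.0, peak_iu=90.0)
            stack, _ = make_angio_stack([art, ven], ANGIO_GEOMETRY, seed=k)
            ta = roi_intensity_curve(stack, art.roi)
            tv = roi_intensity_curve(stack, ven.roi)
            estimates.append(peak_to_peak(ta, tv))
        assert all(a > b for a, b in zip(estimates[:-1], estimates[1:]))


class TestSlopeToMax:
    def test_linear_ramp_closed_form(self):
        spec = BolusSpec(roi=rect_roi("artery", 10, 10), arrival_s=1.0,
                         rise_tau_s=2.0, peak_iu=110.0, baseline_iu=10.0)
        stack, _ = make_angio_stack([spec], ANGIO_GEOMETRY, seed=0)
        trace = roi_intensity_curve(stack, spec.roi)
        assert slope_to_max(trace) == pytest.approx(50.0, rel=0.05)

    def test_slope_doubles_with_peak(self):
        slopes = []
        for peak in (60.0, 110.0):
            spec = BolusSpec(roi=rect_roi("artery", 10, 10), arrival_s=1.0,
                             rise_tau_s=2.0, peak_iu=peak, baseline_iu=10.0)
            stack, _ = make_angio_stack([spec], ANGIO_GEOMETRY, seed=0)
            slopes.append(slope_to_max(roi_intensity_curve(stack, spec.roi)))
        assert slopes[1] / slopes[0] == pytest.approx(2.0, rel=0.05)

    def test_flat_trace_errors(self):
        stack = ImageStack(np.full((30, 32, 32), 42.0), 1.0, FRAME)
        with pytest.warns(UserWarning):
            trace = roi_intensity_curve(stack, rect_roi("artery", 5, 5, shape=(32, 32)))
        with pytest.raises(ValueError, match="rise"):
            slope_to_max(trace)


class TestInvariances:
    def test_offset_invariance(self, bolus_pair):
        """Adding a constant to all frames leaves p2p and slope unchanged."""
        stack, (art, ven), _ = bolus_pair
        shifted = ImageStack(stack.frames + 37.0, stack.pixel_size_um, stack.frame_interval_s)
        m0 = transit_metrics(roi_intensity_curve(stack, art.roi),
                             roi_intensity_curve(stack, ven.roi))
        m1 = transit_metrics(roi_intensity_curve(shifted, art.roi),
                             roi_intensity_curve(shifted, ven.roi))
        assert m0.p2p_interval_s == pytest.approx(m1.p2p_interval_s)
        for label in m0.slope_to_max_iu_per_s:
            assert m0.slope_to_max_iu_per_s[label] == pytest.approx(
                m1.slope_to_max_iu_per_s[label]
            )

    def test_time_shift_leaves_p2p_unchanged(self, bolus_pair):
        stack, (art, ven), _ = bolus_pair
        shifted = ImageStack(stack.frames, stack.pixel_size_um,
                             stack.frame_interval_s, t0_s=5.0)
        p0 = peak_to_peak(roi_intensity_curve(stack, art.roi),
                          roi_intensity_curve(stack, ven.roi))
        p1 = peak_to_peak(roi_intensity_curve(shifted, art.roi),
                          roi_intensity_curve(shifted, ven.roi))
        assert p1 == pytest.approx(p0)
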
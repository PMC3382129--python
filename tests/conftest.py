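import numpy as np
import pytest

from sphenostim.io_core import ROI
from sphenostim.synthetic_data import (
    BolusSpec,
    StackGeometry,
    VesselSpec,
    make_angio_stack,
    make_vessel_stack,
)

ANGIO_GEOMETRY = StackGeometry(frame_interval_s=1.0 / 30.0, n_frames=240)


def rect_roi(label: str, r0: int, c0: int, size: int = 10, shape=(96, 96)) -> ROI:
    mask = np.zeros(shape, dtype=bool)
    mask[r0 : r0 + size, c0 : c0 + size] = True
    return ROI(label=label, mask=mask)


@pytest.fixture
def horizontal_vessel():
    """Noiseless straight horizontal vessel, 20 um at 1 um/px."""
    spec = VesselSpec(centerline=[(48.5, 8.0), (48.5, 88.0)], diameter_um=20.0)
    stack, truth = make_vessel_stack(spec, StackGeometry(n_frames=3), seed=0)
    return stack, truth


@pytest.fixture
def bolus_pair():
    """Arterial peak at 2.0 s, venous at 3.5 s, noiseless."""
    art = BolusSpec(roi=rect_roi("artery", 10, 10), arrival_s=1.0, rise_tau_s=1.0,
                    peak_iu=110.0, baseline_iu=10.0)
    ven = BolusSpec(roi=rect_roi("vein", 50, 50), arrival_s=2.5, rise_tau_s=1.0,
                    peak_iu=90.0, baseline_iu=10.0)
    stack, truth = make_angio_stack([art, ven], ANGIO_GEOMETRY, seed=0)
    return stack, (art, ven), truth
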
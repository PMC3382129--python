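"""Evans-blue BBB quantification and lesion volumetry.

Evans-blue extravasation is scored on RGB dorsal-cortex photographs as
the mean blue-channel intensity over the treated hemisphere and the
percentage of treated-hemisphere pixels whose blue value exceeds a
caller-supplied fixed threshold (the threshold has no default and is
recorded in provenance). Cortical-volume loss is the pixel-count
deficit of the ipsilateral neocortex relative to the contralateral
hemisphere, summed over equal-thickness serial coronal sections so
that the area sum stands in for volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EvansBlueResult",
    "LesionVolumeResult",
    "quantify_evans_blue",
    "cortical_volume_change",
]


@dataclass
class EvansBlueResult:
    mean_blue: float
    pct_blue_pixels: float
    fixed_threshold: float
    n_pixels: int


@dataclass
class LesionVolumeResult:
    per_section: pd.DataFrame  # ipsi_px, contra_px, pct_loss
    aggregate_pct_loss: float
    n_sections: int

    def __post_init__(self) -> None:
        # aggregate must agree with the per-section sums (recomputed check)
        agg = 100.0 * (1.0 - self.per_section.ipsi_px.sum() / self.per_section.contra_px.sum())
        if not np.isclose(agg, self.aggregate_pct_loss):
            raise ValueError("aggregate_pct_loss inconsistent with per-section counts")


def quantify_evans_blue(
    img: np.ndarray, treated_mask: np.ndarray, fixed_threshold: float
) -> EvansBlueResult:
    """Mean blue intensity and % supra-threshold blue pixels in the
    treated hemisphere.

    ``img`` is H×W×3 RGB; the blue channel is the third component.
    The mean is taken over the whole treated-hemisphere mask, and
    ``pct_blue_pixels`` counts pixels with blue value strictly above
    ``fixed_threshold``.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {img.shape}")
    mask = np.asarray(treated_mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {img.shape[:2]}"
        )
    if not mask.any():
        raise ValueError("treated-hemisphere mask is empty")
    blue = img[..., 2].astype(float)[mask]
    return EvansBlueResult(
        mean_blue=float(blue.mean()),
        pct_blue_pixels=100.0 * float(np.mean(blue > fixed_threshold)),
        fixed_threshold=float(fixed_threshold),
        n_pixels=int(mask.sum()),
    )


def cortical_volume_change(sections) -> LesionVolumeResult:
    """Cortical-volume loss from serial sections.

    ``sections`` is a sequence of ``(image, ipsi_mask, contra_mask)``
    triples (the image may be ``None``). Per-section loss is
    ``100 * (1 - ipsi_px / contra_px)``; the aggregate divides the
    summed ipsilateral pixel count by the summed contralateral count,
    weighting each section by its area as the volume proxy across
    equal-thickness sections.
    """
    sections = list(sections)
    if not sections:
        raise ValueError("need at least one section")
    rows = []
    for k, entry in enumerate(sections):
        if len(entry) == 3:
            img, ipsi, contra = entry
        else:
            img, (ipsi, contra) = None, entry
        ipsi = np.asarray(ipsi, dtype=bool)
        contra = np.asarray(contra, dtype=bool)
        if img is not None and ipsi.shape != np.asarray(img).shape[:2]:
            raise ValueError(f"section {k}: mask does not fit image")
        if ipsi.shape != contra.shape:
            raise ValueError(f"section {k}: ipsi/contra mask shapes differ")
        contra_px = int(contra.sum())
        if contra_px == 0:
            raise ValueError(f"section {k}: contralateral mask is empty")
        ipsi_px = int(ipsi.sum())
        rows.append(
            dict(section=k, ipsi_px=ipsi_px, contra_px=contra_px,
                 pct_loss=100.0 * (1.0 - ipsi_px / contra_px))
        )
    df = pd.DataFrame(rows)
    aggregate = 100.0 * (1.0 - df.ipsi_px.sum() / df.contra_px.sum())
    return LesionVolumeResult(per_section=df, aggregate_pct_loss=aggregate, n_sections=len(df))
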
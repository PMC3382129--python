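"""Seeded generators for every input modality, with programmed ground truth.

Each generator returns both the synthetic raw data (image stack, time
series, RGB photograph) and a truth table sufficient to score the
corresponding estimator without re-deriving truth from the rendered
data. All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_core import ImageStack, ROI, TimeSeries

__all__ = [
    "StackGeometry",
    "VesselSpec",
    "BolusSpec",
    "EcogSpec",
    "EcogEvent",
    "make_vessel_stack",
    "make_angio_stack",
    "make_ecog",
    "make_evansblue_image",
    "make_coronal_sections",
]


@dataclass
class StackGeometry:
    """Shared raster geometry for synthetic image stacks."""

    shape: tuple[int, int] = (96, 96)
    pixel_size_um: float = 1.0
    frame_interval_s: float = 2.0
    n_frames: int = 10


# ---------------------------------------------------------------------------
# Pial-vessel diameter stacks
# ---------------------------------------------------------------------------

@dataclass
class VesselSpec:
    """Ground-truth description of one rendered vessel.

    ``diameter_um`` may be a scalar (constant), a length-T array
    (per-frame diameter, constant along the vessel) or a callable
    ``f(arclength_um, t_s) -> um``. The vessel is rendered as a ridge
    with rectangular (top-hat) cross-section of the true local width
    and a 1-px anti-aliased border, so the true diameter is
    unambiguous.
    """

    centerline: Sequence[tuple[float, float]]
    diameter_um: float | np.ndarray | Callable[[float, float], float] = 20.0
    contrast: float = 100.0
    background: float = 20.0
    noise_sd: float = 0.0

    def diameter_fn(self, geometry: StackGeometry) -> Callable[[np.ndarray, float], np.ndarray]:
        d = self.diameter_um
        if callable(d):
            return lambda s, t: np.asarray([d(si, t) for si in np.atleast_1d(s)], dtype=float)
        if np.ndim(d) == 1:
            arr = np.asarray(d, dtype=float)
            if arr.size != geometry.n_frames:
                raise ValueError(
                    f"per-frame diameter array has {arr.size} entries for "
                    f"{geometry.n_frames} frames"
                )

            def fn(s, t, _arr=arr, _dt=geometry.frame_interval_s):
                i = int(round(t / _dt))
                return np.full(np.atleast_1d(s).shape, _arr[i], dtype=float)

            return fn
        val = float(d)
        return lambda s, t: np.full(np.atleast_1d(s).shape, val, dtype=float)


def _polyline_distance(shape: tuple[int, int], verts: np.ndarray):
    """Per-pixel distance to a polyline and arclength of the projection."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    best_d = np.full(pts.shape[0], np.inf)
    best_s = np.zeros(pts.shape[0])
    s0 = 0.0
    for a, b in zip(verts[:-1], verts[1:]):
        ab = b - a
        seg_len = float(np.hypot(*ab))
        if seg_len == 0:
            continue
        t = np.clip(((pts - a) @ ab) / seg_len**2, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.hypot(pts[:, 0] - proj[:, 0], pts[:, 1] - proj[:, 1])
        closer = d < best_d
        best_d[closer] = d[closer]
        best_s[closer] = s0 + t[closer] * seg_len
        s0 += seg_len
    return best_d.reshape(shape), best_s.reshape(shape), s0


def make_vessel_stack(
    spec: VesselSpec,
    geometry: StackGeometry | None = None,
    seed: int = 0,
    n_points: int = 5,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a vessel-diameter imaging stack plus its truth table.

    Returns the stack and a DataFrame with columns ``frame, point_id,
    arclength_um, row, col, diam_um`` giving the programmed local
    diameter at ``n_points`` equidistant interior points for every
    frame. The point coordinates lie on the programmed centerline and
    can be fed directly to the morphometry stage.
    """
    geometry = geometry or StackGeometry()
    rng = np.random.default_rng(seed)
    verts = np.asarray(spec.centerline, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 2:
        raise ValueError("centerline needs at least two (row, col) vertices")
    H, W = geometry.shape
    if (verts < 0).any() or (verts[:, 0] > H - 1).any() or (verts[:, 1] > W - 1).any():
        raise ValueError("centerline exceeds image bounds")

    dist_px, arclen_px, total_len_px = _polyline_distance(geometry.shape, verts)
    arclen_um = arclen_px * geometry.pixel_size_um
    diam_fn = spec.diameter_fn(geometry)

    # interior measurement points: equidistant arclengths away from the ends
    fracs = (np.arange(n_points) + 1) / (n_points + 1)
    point_s_px = fracs * total_len_px
    point_coords = _points_on_polyline(verts, point_s_px)

    frames = np.empty((geometry.n_frames, H, W), dtype=float)
    truth_rows = []
    for i in range(geometry.n_frames):
        t = i * geometry.frame_interval_s
        half_w_um = diam_fn(arclen_um.ravel(), t).reshape(geometry.shape) / 2.0
        half_w_px = half_w_um / geometry.pixel_size_um
        if 2 * half_w_px.max() > min(H, W):
            raise ValueError("vessel wider than image")
        # top-hat ridge, 1-px anti-aliased border
        coverage = np.clip(half_w_px - dist_px + 0.5, 0.0, 1.0)
        frame = spec.background + spec.contrast * coverage
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, size=frame.shape)
        frames[i] = frame
        d_pts = diam_fn(point_s_px * geometry.pixel_size_um, t)
        for j, (s_px, (r, c)) in enumerate(zip(point_s_px, point_coords)):
            truth_rows.append(
                dict(
                    frame=i,
                    point_id=j,
                    arclength_um=s_px * geometry.pixel_size_um,
                    row=r,
                    col=c,
                    diam_um=float(d_pts[j]),
                )
            )

    stack = ImageStack(
        frames=frames,
        pixel_size_um=geometry.pixel_size_um,
        frame_interval_s=geometry.frame_interval_s,
    )
    return stack, pd.DataFrame(truth_rows)


def _points_on_polyline(verts: np.ndarray, arclens: np.ndarray) -> np.ndarray:
    seg = np.diff(verts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    out = np.empty((len(arclens), 2))
    for k, s in enumerate(arclens):
        i = min(np.searchsorted(cum, s, side="right") - 1, len(seg_len) - 1)
        frac = (s - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
        out[k] = verts[i] + frac * seg[i]
    return out


# ---------------------------------------------------------------------------
# Fluorescent-angiography bolus stacks
# ---------------------------------------------------------------------------

@dataclass
class BolusSpec:
    """Programmed bolus-transit curve for one ROI.

    Intensity follows ``baseline_iu`` until ``arrival_s``, rises to
    ``peak_iu`` over ``rise_tau_s`` (linear ramp or gamma-variate),
    then decays exponentially with ``decay_tau_s``.
    """

    roi: ROI
    arrival_s: float
    rise_tau_s: float
    peak_iu: float
    baseline_iu: float = 10.0
    decay_tau_s: float = 5.0
    shape: str = "linear"  # or "gamma"
    gamma_alpha: float = 3.0

    def __post_init__(self) -> None:
        if self.arrival_s < 0:
            raise ValueError("arrival_s must be >= 0")
        if not self.peak_iu > self.baseline_iu >= 0:
            raise ValueError("need peak_iu > baseline_iu >= 0")
        if self.shape not in ("linear", "gamma"):
            raise ValueError(f"unknown bolus shape {self.shape!r}")

    def curve(self, t: np.ndarray) -> np.ndarray:
        tt = np.asarray(t, dtype=float)
        amp = self.peak_iu - self.baseline_iu
        out = np.full(tt.shape, self.baseline_iu)
        rel = tt - self.arrival_s
        if self.shape == "linear":
            rising = (rel >= 0) & (rel < self.rise_tau_s)
            out[rising] += amp * rel[rising] / self.rise_tau_s
        else:
            a = self.gamma_alpha
            rising = (rel >= 0) & (rel < self.rise_tau_s)
            x = rel[rising] / self.rise_tau_s
            out[rising] += amp * np.power(x, a) * np.exp(a * (1 - x))
        falling = rel >= self.rise_tau_s
        out[falling] += amp * np.exp(-(rel[falling] - self.rise_tau_s) / self.decay_tau_s)
        return out

    @property
    def peak_time_s(self) -> float:
        return self.arrival_s + self.rise_tau_s

    @property
    def slope_iu_per_s(self) -> float:
        """Programmed mean rise slope (amplitude over rise time)."""
        return (self.peak_iu - self.baseline_iu) / self.rise_tau_s


def make_angio_stack(
    specs: Sequence[BolusSpec],
    geometry: StackGeometry | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    background_iu: float = 5.0,
) -> tuple[ImageStack, dict]:
    """Render a 30 fps angiography stack from per-ROI bolus curves.

    ROIs must be pairwise disjoint. Returns the stack and a truth dict
    with per-label peak times and slopes plus the programmed
    venous-minus-arterial peak-to-peak interval for every
    (artery, vein) label pair.
    """
    geometry = geometry or StackGeometry(frame_interval_s=1.0 / 30.0, n_frames=240)
    rng = np.random.default_rng(seed)
    H, W = geometry.shape
    masks = [s.roi.to_mask((H, W)) for s in specs]
    union = np.zeros((H, W), dtype=int)
    for m in masks:
        union += m
    if (union > 1).any():
        raise ValueError("ROIs overlap; bolus specs must use disjoint ROIs")

    t = np.arange(geometry.n_frames) * geometry.frame_interval_s
    frames = np.full((geometry.n_frames, H, W), background_iu, dtype=float)
    for spec, mask in zip(specs, masks):
        curve = spec.curve(t)
        frames[:, mask] = curve[:, None]
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)

    truth: dict = {
        "peak_time_s": {s.roi.label: s.peak_time_s for s in specs},
        "slope_iu_per_s": {s.roi.label: s.slope_iu_per_s for s in specs},
        "baseline_iu": {s.roi.label: s.baseline_iu for s in specs},
    }
    arteries = [s for s in specs if s.roi.label == "artery"]
    veins = [s for s in specs if s.roi.label == "vein"]
    if arteries and veins:
        truth["p2p_interval_s"] = veins[0].peak_time_s - arteries[0].peak_time_s
    stack = ImageStack(
        frames=frames,
        pixel_size_um=geometry.pixel_size_um,
        frame_interval_s=geometry.frame_interval_s,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# ECoG
# ---------------------------------------------------------------------------

@dataclass
class EcogEvent:
    """One injected high-amplitude fast event.

    The carrier is drawn uniformly from ``carrier_band_hz``; set both
    edges equal for a fixed carrier frequency.
    """

    onset_s: float
    duration_s: float
    amplitude_multiple: float = 5.0  # × background SD, envelope peak
    carrier_band_hz: tuple[float, float] = (71.0, 90.0)


@dataclass
class EcogSpec:
    """Synthetic epidural ECoG: 1/f^alpha background plus injected events.

    Defaults emulate rodent epidural ECoG: pink background
    (``alpha = 1``) with 50 µV RMS, band-limited to 2–90 Hz, sampled at
    1 kHz. Events are band-limited bursts whose envelope peaks at
    ``amplitude_multiple`` × background SD.
    """

    fs_hz: float = 1000.0
    duration_s: float = 600.0
    alpha: float = 1.0
    rms_uv: float = 50.0
    band_hz: tuple[float, float] = (2.0, 90.0)
    events: Sequence[EcogEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.amplitude_multiple <= 0:
                raise ValueError("amplitude_multiple must be > 0")
            if ev.onset_s < 0 or ev.onset_s + ev.duration_s > self.duration_s:
                raise ValueError(
                    f"event at {ev.onset_s}s (+{ev.duration_s}s) does not fit "
                    f"in {self.duration_s}s recording"
                )
            lo, hi = ev.carrier_band_hz
            if not (0 < lo <= hi < self.fs_hz / 2):
                raise ValueError("carrier band must lie within (0, fs/2)")


def make_ecog(spec: EcogSpec, seed: int = 0) -> tuple[TimeSeries, pd.DataFrame]:
    """Synthesise an ECoG record and return it with its true event list.

    The background is white noise shaped in the frequency domain to a
    1/f^alpha spectrum with support restricted to ``band_hz``, scaled
    to ``rms_uv``. Each event adds a Tukey-windowed sinusoidal burst at
    a carrier drawn uniformly from its band, with envelope peak
    ``amplitude_multiple × rms_uv``.
    """
    from scipy.signal.windows import tukey

    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.fs_hz))
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs_hz)
    spec_shape = np.zeros_like(freqs)
    lo, hi = spec.band_hz
    in_band = (freqs >= lo) & (freqs <= hi)
    spec_shape[in_band] = freqs[in_band] ** (-spec.alpha / 2.0)

    white = rng.standard_normal(n)
    shaped = np.fft.irfft(np.fft.rfft(white) * spec_shape, n=n)
    shaped *= spec.rms_uv / np.std(shaped)

    truth_rows = []
    for ev in spec.events:
        i0 = int(round(ev.onset_s * spec.fs_hz))
        m = int(round(ev.duration_s * spec.fs_hz))
        carrier_hz = rng.uniform(*ev.carrier_band_hz)
        phase = rng.uniform(0, 2 * np.pi)
        tt = np.arange(m) / spec.fs_hz
        env = tukey(m, alpha=0.25)
        burst = ev.amplitude_multiple * spec.rms_uv * env * np.sin(
            2 * np.pi * carrier_hz * tt + phase
        )
        shaped[i0 : i0 + m] += burst
        truth_rows.append(
            dict(
                onset_s=ev.onset_s,
                duration_s=ev.duration_s,
                amplitude_multiple=ev.amplitude_multiple,
                carrier_hz=carrier_hz,
            )
        )
    ts = TimeSeries(shaped, fs_hz=spec.fs_hz, unit="ecog_uv")
    cols = ["onset_s", "duration_s", "amplitude_multiple", "carrier_hz"]
    return ts, pd.DataFrame(truth_rows, columns=cols)


# ---------------------------------------------------------------------------
# Evans-blue dorsal-cortex photographs
# ---------------------------------------------------------------------------

def make_evansblue_image(
    extravasation_fraction: float,
    intensity_level: int = 180,
    shape: tuple[int, int] = (120, 160),
    background_blue: int = 60,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, np.ndarray], dict]:
    """Synthetic dorsal-cortex RGB photograph with an Evans-blue blob.

    The image is split into a treated (left) and control (right)
    hemisphere mask. A compact blob occupying exactly
    ``extravasation_fraction`` of the treated-hemisphere pixels has its
    blue channel raised to ``intensity_level``; elsewhere the blue
    channel sits at ``background_blue``. Truth records the programmed
    fraction and mean blue value inside the blob.
    """
    if not 0.0 <= extravasation_fraction <= 1.0:
        raise ValueError("extravasation_fraction must be in [0, 1]")
    if not 0 <= background_blue < intensity_level <= 255:
        raise ValueError("need 0 <= background_blue < intensity_level <= 255")
    rng = np.random.default_rng(seed)
    H, W = shape
    treated = np.zeros((H, W), dtype=bool)
    treated[:, : W // 2] = True
    control = ~treated

    img = np.zeros((H, W, 3), dtype=float)
    img[..., 0] = 120.0  # red: fixed cortical tone
    img[..., 1] = 90.0
    img[..., 2] = float(background_blue)

    n_blob = int(round(extravasation_fraction * treated.sum()))
    blob = np.zeros((H, W), dtype=bool)
    if n_blob > 0:
        rr, cc = np.mgrid[0:H, 0:W]
        center = (H / 2.0, W / 4.0)
        d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
        d2 = np.where(treated, d2, np.inf)
        order = np.argsort(d2.ravel(), kind="stable")[:n_blob]
        blob.ravel()[order] = True
        img[..., 2][blob] = float(intensity_level)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    truth = {
        "extravasation_fraction": extravasation_fraction,
        "n_blob_px": n_blob,
        "mean_blue_in_blob": float(intensity_level) if n_blob else float("nan"),
        "background_blue": float(background_blue),
        "expected_mean_blue_treated": (
            (n_blob * intensity_level + (treated.sum() - n_blob) * background_blue)
            / treated.sum()
        ),
    }
    return img, {"treated": treated, "control": control, "blob": blob}, truth


# ---------------------------------------------------------------------------
# Coronal sections for lesion volumetry
# ---------------------------------------------------------------------------

def make_coronal_sections(
    n_sections: int = 6,
    loss_fraction: float | Sequence[float] = 0.371,
    shape: tuple[int, int] = (100, 140),
    seed: int = 0,
) -> tuple[list[tuple[np.ndarray, np.ndarray, np.ndarray]], dict]:
    """Synthetic cresyl-violet coronal sections with programmed cortical loss.

    Each section yields ``(rgb_image, ipsi_cortex_mask, contra_cortex_mask)``.
    The contralateral cortex mask has a fixed pixel area A; the
    ipsilateral mask keeps ``round((1 - loss) * A)`` pixels. Truth
    records per-section and aggregate loss computed from the actual
    mask pixel counts.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    losses = np.broadcast_to(np.asarray(loss_fraction, dtype=float), (n_sections,)).copy()
    if (losses < 0).any() or (losses >= 1).any():
        raise ValueError("loss_fraction must be in [0, 1)")
    H, W = shape
    # contralateral cortical band: right hemisphere, fixed rectangle
    band_rows = slice(H // 5, H // 5 + H // 3)
    contra_cols = slice(W // 2 + 5, W - 8)
    sections = []
    per_section = []
    for losses_i in losses:
        contra = np.zeros((H, W), dtype=bool)
        contra[band_rows, contra_cols] = True
        area = int(contra.sum())
        keep = int(round((1.0 - losses_i) * area))
        ipsi = np.zeros((H, W), dtype=bool)
        # mirror of the contra band, truncated in raster order to `keep` px
        mirror = contra[:, ::-1]
        idx = np.flatnonzero(mirror.ravel())[:keep]
        ipsi.ravel()[idx] = True
        img = np.full((H, W, 3), 230, dtype=np.uint8)  # pale section background
        img[contra | ipsi] = (120, 60, 140)  # cresyl-violet stained cortex
        sections.append((img, ipsi, contra))
        per_section.append(
            dict(ipsi_px=int(ipsi.sum()), contra_px=area,
                 pct_loss=100.0 * (1.0 - ipsi.sum() / area))
        )
    df = pd.DataFrame(per_section)
    truth = {
        "per_section": df,
        "aggregate_pct_loss": 100.0 * (1.0 - df.ipsi_px.sum() / df.contra_px.sum()),
        "programmed_loss_fraction": losses,
    }
    return sections, truth
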
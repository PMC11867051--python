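"""Vessel-centric quantification of puff-evoked perivascular Ca2+ signals.

Two readouts are produced from each two-channel movie:

1. dF/F0 of a region of interest around the capillary,
   ``dF/F0 = (F - F0) / F0``, with F0 the pre-puff baseline mean — a gross
   measure of indicator loading and responsivity.

2. A vessel-centric radial profile: baseline and peak frame averages are
   formed (9 frames each by default), their difference isolates the evoked
   response, bright Mueller-stalk pixels are masked out (top-percentile
   threshold on the peak average, dilated, converted to NaN), the field is
   straightened along the vessel, collapsed along the vessel axis into a
   signed-distance profile, and converted to z-scores ``z = dF / sigma``.
   The sheath readout is the mean of the two per-side peak z-scores
   adjacent to the vessel, ``ave_peak_z = (left_peak + right_peak) / 2``.

sigma is, by default, the pooled per-pixel standard deviation of the
individual baseline frames about their mean — a noise-floor estimate
independent of the evoked signal (see :func:`estimate_sigma_temporal`).
A far-field spatial estimate and an explicit override are available.

The vessel channel is carried through the same straighten/collapse geometry
and rescaled so its profile maximum is exactly 5 (a display convention:
vessel fluorescence rendered at z = 5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import (
    StraightenedImage,
    VesselSegment,
    polyline_distance_map,
    segment_vessel,
    straighten,
)
from .synthetic import TwoChannelMovie


class QuantError(ValueError):
    pass


class MaskedColumnError(QuantError):
    """A straightened column contained no usable samples after masking."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            f"column(s) {self.columns} entirely excluded after masking; "
            "widen the field or reject the vessel"
        )


@dataclass
class QuantConfig:
    """Tunable parameters of the quantification pipeline (defaults follow
    the analysis conventions described in docs/methods.md)."""

    n_avg_frames: int = 9  # frames averaged for baseline and peak images
    stalk_percentile: float = 3.0  # top-% of peak-average pixels masked
    dilation_iterations: int = 2  # 3x3 full-neighbourhood dilations
    half_width_um: float = 20.0  # profile extent on either side
    peak_search_um: float = 10.0  # peak search window outward from the wall
    roi_halfwidth_um: float | None = None  # None => max(3*diameter, 10 um)
    sigma: float | None = None  # explicit noise-scale override
    sigma_method: str = "temporal"  # "temporal" | "spatial"
    far_field_um: float = 15.0  # |offset| beyond which "spatial" sigma looks


@dataclass
class FrameAverage:
    values: np.ndarray
    frame_indices: list[int]
    role: str  # "baseline" | "peak"


@dataclass
class StalkMask:
    mask: np.ndarray  # True = excluded
    percentile_used: float
    dilation_iterations: int
    threshold_value: float

    @property
    def masked_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class RadialProfile:
    """Signed distance from the vessel center vs. evoked fluorescence."""

    positions_um: np.ndarray
    delta_f: np.ndarray
    z: np.ndarray | None = None
    sigma_used: float | None = None
    vessel_display: np.ndarray | None = None  # vessel profile, max rescaled to 5


@dataclass
class SheathMetrics:
    dff: float
    left_peak_z: float
    right_peak_z: float
    ave_peak_z: float
    roi_halfwidth_um: float
    mask_fraction: float
    n_baseline_frames: int
    n_peak_frames: int
    sigma_used: float
    radius_um: float


# ---------------------------------------------------------------------------
# Eq. 1: dF/F0 of a vessel-centered ROI
# ---------------------------------------------------------------------------


def dff_trace(
    movie: TwoChannelMovie,
    segment: VesselSegment,
    roi_halfwidth_um: float,
) -> tuple[np.ndarray, float]:
    """Per-frame dF/F0 of the ROI within ``roi_halfwidth_um`` of the vessel
    center, and its post-onset peak.

    F0 is the ROI mean over all frames preceding the puff onset.
    """
    if roi_halfwidth_um <= 0:
        raise QuantError("roi_halfwidth_um must be positive")
    onset = movie.puff_onset_frame
    if onset < 1:
        raise QuantError("baseline period (frames before puff onset) is empty")
    dist_px = polyline_distance_map(movie.glial.shape[1:], segment.centerline)
    roi = dist_px * movie.pixel_size_um <= roi_halfwidth_um
    f = movie.glial[:, roi].mean(axis=1)
    f0 = f[:onset].mean()
    if f0 <= 0:
        raise QuantError(f"baseline F0 = {f0} <= 0: uncalibrated input")
    series = (f - f0) / f0
    peak = float(series[onset:].max())
    return series, peak


# ---------------------------------------------------------------------------
# frame averaging
# ---------------------------------------------------------------------------


def frame_average(
    stack: np.ndarray,
    role: str,
    puff_onset_frame: int,
    n_frames: int = 9,
    peak_frame: int | None = None,
) -> FrameAverage:
    """Average ``n_frames`` movie frames into a baseline or peak image.

    baseline: the n_frames frames immediately preceding the puff onset.
    peak: n_frames centered on ``peak_frame`` (the argmax of the dF/F0
    series), clipped to the recording; the indices used are recorded.
    """
    t = stack.shape[0]
    if role == "baseline":
        if puff_onset_frame < n_frames:
            raise QuantError(
                f"baseline needs {n_frames} frames before onset, only "
                f"{puff_onset_frame} available"
            )
        idx = list(range(puff_onset_frame - n_frames, puff_onset_frame))
    elif role == "peak":
        if peak_frame is None:
            raise QuantError("peak averaging requires peak_frame")
        lo = max(0, peak_frame - n_frames // 2)
        hi = min(t, lo + n_frames)
        lo = max(0, hi - n_frames)
        idx = list(range(lo, hi))
        if not idx:
            raise QuantError("no frames available around the peak")
    else:
        raise QuantError(f"unknown role {role!r}")
    return FrameAverage(values=stack[idx].mean(axis=0), frame_indices=idx, role=role)


# ---------------------------------------------------------------------------
# stalk masking
# ---------------------------------------------------------------------------


def stalk_mask(
    peak_avg: FrameAverage | np.ndarray,
    percentile: float = 3.0,
    dilation_iterations: int = 2,
) -> StalkMask:
    """Mask bright Mueller-stalk pixels.

    Pixels strictly above the (100 - percentile)-th percentile of the
    averaged peak image (not baseline subtracted) are masked, then the
    binary mask is dilated ``dilation_iterations`` times with a full 3x3
    neighbourhood.  Strict inequality means a constant image yields an
    empty mask.
    """
    if not 0 < percentile < 100:
        raise QuantError(f"percentile must lie in (0, 100), got {percentile}")
    values = peak_avg.values if isinstance(peak_avg, FrameAverage) else peak_avg
    thr = float(np.percentile(values, 100.0 - percentile))
    mask = values > thr
    if dilation_iterations > 0 and mask.any():
        mask = ndimage.binary_dilation(
            mask, structure=np.ones((3, 3), bool), iterations=dilation_iterations
        )
    return StalkMask(
        mask=mask,
        percentile_used=percentile,
        dilation_iterations=dilation_iterations,
        threshold_value=thr,
    )


def apply_mask(image: np.ndarray, mask: StalkMask | np.ndarray) -> np.ndarray:
    """Set masked pixels to NaN (the excluded-value marker)."""
    m = mask.mask if isinstance(mask, StalkMask) else mask
    out = np.asarray(image, dtype=float).copy()
    out[m] = np.nan
    return out


# ---------------------------------------------------------------------------
# profile collapse and z-scoring
# ---------------------------------------------------------------------------


def collapse_profile(straightened: StraightenedImage) -> RadialProfile:
    """Collapse a straightened dF image along the vessel axis.

    Each column (signed distance) is averaged over all non-excluded rows.
    A column with no usable samples is an error: the caller must widen the
    field or reject the vessel.
    """
    vals = straightened.values
    empty = np.where(np.all(np.isnan(vals), axis=0))[0]
    if len(empty):
        raise MaskedColumnError(empty)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        prof = np.nanmean(vals, axis=0)
    return RadialProfile(positions_um=straightened.offsets_um, delta_f=prof)


def estimate_sigma_temporal(baseline_frames: np.ndarray) -> float:
    """Noise scale from individual baseline frames.

    ``baseline_frames`` is a (n_frames, H, W) stack of pre-stimulus frames
    (masked pixels NaN).  At every pixel the unbiased variance across
    frames is taken; sigma is the square root of the pooled mean variance —
    the per-pixel single-frame noise floor, estimated before any evoked
    signal exists and free of interpolation effects.
    """
    if baseline_frames.shape[0] < 2:
        raise QuantError("need >= 2 baseline frames for a temporal sigma")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_pixel = np.nanvar(baseline_frames, axis=0, ddof=1)
        pooled = np.nanmean(per_pixel)
    return float(np.sqrt(pooled))


def estimate_sigma_spatial(profile: RadialProfile, far_field_um: float = 15.0) -> float:
    """Alternative noise scale: SD of the collapsed dF profile in the far
    field (|offset| > far_field_um), where no sheath signal is expected.
    Note this measures noise at the collapsed-profile scale, not the
    per-pixel scale."""
    far = np.abs(profile.positions_um) > far_field_um
    if far.sum() < 2:
        raise QuantError("far field too small for a spatial sigma")
    return float(np.nanstd(profile.delta_f[far], ddof=1))


def zscore_profile(
    profile: RadialProfile,
    baseline_frames: np.ndarray | None = None,
    sigma: float | None = None,
    method: str = "temporal",
    far_field_um: float = 15.0,
) -> RadialProfile:
    """Convert a dF profile to z-scores, z = dF / sigma, with one scalar
    sigma per profile.  ``sigma_used`` is recorded on the result."""
    if sigma is None:
        if method == "temporal":
            if baseline_frames is None:
                raise QuantError("temporal sigma requires baseline frames")
            sigma = estimate_sigma_temporal(baseline_frames)
        elif method == "spatial":
            sigma = estimate_sigma_spatial(profile, far_field_um)
        else:
            raise QuantError(f"unknown sigma method {method!r}")
    if sigma <= 0 or not np.isfinite(sigma):
        raise QuantError(
            f"sigma = {sigma}: noise-free or degenerate input; pass an "
            "explicit sigma override"
        )
    return replace(profile, z=profile.delta_f / sigma, sigma_used=float(sigma))


def peak_zscores(
    profile: RadialProfile,
    segment: VesselSegment,
    search_window_um: float = 10.0,
) -> tuple[float, float, float]:
    """Per-side peak z adjacent to the vessel and their average.

    The search windows run from the vessel wall (r_v) outward by
    ``search_window_um`` on each side; lumen samples are excluded.
    Returns (left_peak_z, right_peak_z, ave_peak_z) with
    ave = (left + right) / 2 exactly.
    """
    if profile.z is None:
        raise QuantError("profile has no z values; run zscore_profile first")
    rv = segment.radius_um
    pos = profile.positions_um
    left = (pos <= -rv) & (pos >= -(rv + search_window_um))
    right = (pos >= rv) & (pos <= rv + search_window_um)
    if not left.any() or not right.any():
        raise QuantError("empty peak-search window adjacent to the vessel")
    lp = float(np.nanmax(profile.z[left]))
    rp = float(np.nanmax(profile.z[right]))
    return lp, rp, (lp + rp) / 2.0


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------


def quantify_movie(
    movie: TwoChannelMovie,
    config: QuantConfig | None = None,
    segment: VesselSegment | None = None,
) -> tuple[SheathMetrics, RadialProfile]:
    """Run the full vessel-centric quantification on one movie.

    Stages: vessel segmentation -> dF/F0 trace -> baseline / peak frame
    averages -> baseline subtraction -> stalk mask (on the peak average) ->
    mask application -> straightening -> axis collapse -> z-scoring ->
    bilateral peak averaging.  The vessel channel is collapsed through the
    same geometry and rescaled so its profile maximum is exactly 5.
    """
    cfg = config or QuantConfig()
    try:
        if segment is None:
            segment = segment_vessel(movie.vessel, movie.pixel_size_um)
        if not segment.in_focus:
            raise QuantError("vessel flagged as out of focus")
    except Exception as e:
        raise QuantError(f"segmentation stage: {e}") from e

    roi_hw = cfg.roi_halfwidth_um
    if roi_hw is None:
        roi_hw = max(3.0 * segment.diameter_um, 10.0)
    series, dff_peak = dff_trace(movie, segment, roi_hw)
    peak_frame = int(movie.puff_onset_frame + np.argmax(series[movie.puff_onset_frame:]))

    base = frame_average(
        movie.glial, "baseline", movie.puff_onset_frame, cfg.n_avg_frames
    )
    peak = frame_average(
        movie.glial,
        "peak",
        movie.puff_onset_frame,
        cfg.n_avg_frames,
        peak_frame=peak_frame,
    )
    evoked = peak.values - base.values

    mask = stalk_mask(peak, cfg.stalk_percentile, cfg.dilation_iterations)
    evoked_masked = apply_mask(evoked, mask)

    try:
        st = straighten(evoked_masked, segment, cfg.half_width_um)
        profile = collapse_profile(st)
    except Exception as e:
        raise QuantError(f"straighten/collapse stage: {e}") from e

    if cfg.sigma is None and cfg.sigma_method == "temporal":
        base_frames = movie.glial[base.frame_indices].astype(float)
        base_frames = np.stack([apply_mask(f, mask) for f in base_frames])
        profile = zscore_profile(profile, baseline_frames=base_frames)
    else:
        profile = zscore_profile(
            profile,
            sigma=cfg.sigma,
            method=cfg.sigma_method,
            far_field_um=cfg.far_field_um,
        )

    vessel_prof = collapse_profile(
        straighten(np.asarray(movie.vessel, dtype=float), segment, cfg.half_width_um)
    )
    vmax = np.nanmax(vessel_prof.delta_f)
    if not vmax > 0:
        raise QuantError("vessel channel profile has no positive maximum")
    profile = replace(profile, vessel_display=vessel_prof.delta_f / vmax * 5.0)

    lp, rp, ave = peak_zscores(profile, segment, cfg.peak_search_um)
    metrics = SheathMetrics(
        dff=dff_peak,
        left_peak_z=lp,
        right_peak_z=rp,
        ave_peak_z=ave,
        roi_halfwidth_um=roi_hw,
        mask_fraction=mask.masked_fraction,
        n_baseline_frames=len(base.frame_indices),
        n_peak_frames=len(peak.frame_indices),
        sigma_used=profile.sigma_used,
        radius_um=segment.radius_um,
    )
    return metrics, profile
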
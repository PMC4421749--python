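"""Kymographs and elongation-rate estimation.

A kymograph maps intensity along a path (rows) against time (columns); a
growing tip appears as a sloped edge whose slope is the elongation rate.
Tip localization uses half-max edge detection per column with a width-3
median filter over time; the rate is an ordinary least-squares line through
the tip positions over the longest nondecreasing (growth) interval,
converted to um/min via the pixel size and frame interval.

For motile single filaments whose tips cannot be tracked on a fixed path,
:func:`growth_rate_from_lengths` fits length-vs-time measurements instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats

from .curvature import resample_path
from .imgseg import extract_segments, segment_channel, skeletonize_mask
from .io import ImageStack


@dataclass
class Kymograph:
    matrix: np.ndarray  # (distance along path, time)
    path: np.ndarray    # resampled (row, col) pixel coordinates, 1-px spacing
    pixel_size_um: float
    frame_interval_s: float
    line_width_px: int = 3

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GrowthRateEstimate:
    rate_um_min: float
    intercept_um: float
    r_squared: float
    n_frames_used: int
    method: str  # "kymograph_tip" | "length_series"
    shrinkage_flag: bool = False


def build_kymograph(stack: ImageStack, path, line_width_px: int = 3,
                    smooth_sigma_px: float = 0.0) -> Kymograph:
    """Sample each frame along the arc-length-resampled path.

    Intensity is averaged perpendicular to the path over ``line_width_px``
    with bilinear interpolation for off-grid samples. Raises if the path
    leaves the image, listing the offending vertices. ``smooth_sigma_px``
    smooths a pixelated (skeleton-derived) path first so staircase jitter
    does not inflate the arc-length axis.
    """
    pts = np.asarray(path, dtype=float)
    h, w = stack.frame_shape
    bad = [tuple(p) for p in pts
           if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1)]
    if bad:
        raise ValueError(f"path exits the field at vertices: {bad[:5]}"
                         + ("..." if len(bad) > 5 else ""))
    rs = resample_path(pts, step_px=1.0, smooth_sigma_px=smooth_sigma_px)

    tang = np.gradient(rs, axis=0)
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tang /= norms
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])

    offsets = np.arange(line_width_px, dtype=float) - (line_width_px - 1) / 2.0
    # (n_positions, n_offsets, 2)
    coords = rs[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    flat = coords.reshape(-1, 2).T  # (2, n_positions * n_offsets)

    matrix = np.empty((len(rs), stack.n_frames), dtype=float)
    for t in range(stack.n_frames):
        vals = ndi.map_coordinates(stack.data[t].astype(float), flat,
                                   order=1, mode="nearest")
        matrix[:, t] = vals.reshape(len(rs), line_width_px).mean(axis=1)
    return Kymograph(matrix, rs, stack.pixel_size_um, stack.frame_interval_s,
                     line_width_px)


def kymograph_along_skeleton(stack: ImageStack, line_width_px: int = 3,
                             min_length_px: int = 30,
                             segmentation_kwargs: dict | None = None) -> Kymograph:
    """Kymograph along the longest final-frame skeleton segment.

    The path is oriented so that its start coincides with the filament's
    earliest visible signal (nucleation end), which makes the far edge of
    the kymograph the moving tip.
    """
    kw = segmentation_kwargs or {}
    mask = segment_channel(stack.data[-1], pixel_size_um=stack.pixel_size_um,
                           **kw)
    segs = extract_segments(skeletonize_mask(mask),
                            min_length_px=min_length_px)
    if not segs:
        raise ValueError("no skeleton segment found in the final frame")
    seg = max(segs, key=lambda s: s.n_pixels)
    kymo = build_kymograph(stack, seg.coords, line_width_px=line_width_px,
                           smooth_sigma_px=2.0)

    # orient: earliest column with signal should peak near row 0
    bg = np.median(kymo.matrix)
    excess = kymo.matrix - bg
    col_sig = excess.max(axis=0)
    thr = 0.25 * col_sig.max()
    first = int(np.argmax(col_sig > thr))
    col = excess[:, first].clip(min=0)
    if col.sum() > 0:
        com = float(np.sum(np.arange(len(col)) * col) / col.sum())
        if com > (len(col) - 1) / 2.0:
            kymo = Kymograph(kymo.matrix[::-1].copy(), kymo.path[::-1].copy(),
                             kymo.pixel_size_um, kymo.frame_interval_s,
                             kymo.line_width_px)
    return kymo


def tip_positions(kymo: Kymograph, threshold_frac: float = 0.5):
    """Half-max tip localization per column, median-filtered over time.

    Returns ``(times_s, tips_um)``; columns with no suprathreshold signal
    are NaN (missing values, not errors).
    """
    m = kymo.matrix
    # noise level from the background (sub-median) half, so a signal-rich
    # kymograph does not inflate the detection guard
    bgvals = m[m <= np.median(m)]
    mad = 1.4826 * np.median(np.abs(bgvals - np.median(bgvals)))
    tips_px = np.full(m.shape[1], np.nan)
    for t in range(m.shape[1]):
        col = ndi.uniform_filter1d(m[:, t], size=3, mode="nearest")
        col_bg = np.percentile(col, 10)
        cmax = col.max()
        if cmax - col_bg <= 4.0 * mad or cmax <= col_bg:
            continue
        thr = col_bg + threshold_frac * (cmax - col_bg)
        above = np.nonzero(col >= thr)[0]
        if len(above):
            tips_px[t] = above[-1]
    # width-3 median filter over time, NaN-aware
    filt = tips_px.copy()
    for t in range(len(tips_px)):
        window = tips_px[max(0, t - 1): t + 2]
        window = window[~np.isnan(window)]
        if len(window):
            filt[t] = np.median(window)
    times_s = np.arange(m.shape[1]) * kymo.frame_interval_s
    return times_s, filt * kymo.pixel_size_um


def _longest_nondecreasing(times, values, tol):
    """Indices of the longest window with values nondecreasing within tol."""
    valid = np.nonzero(~np.isnan(values))[0]
    if len(valid) == 0:
        return valid
    best_start = start = 0
    best_len = cur_len = 1
    for i in range(1, len(valid)):
        if values[valid[i]] >= values[valid[i - 1]] - tol:
            cur_len += 1
        else:
            start = i
            cur_len = 1
        if cur_len > best_len:
            best_len = cur_len
            best_start = start
    return valid[best_start: best_start + best_len]


def growth_rate_from_kymograph(kymo: Kymograph,
                               threshold_frac: float = 0.5,
                               monotone_tol_px: float = 1.5) -> GrowthRateEstimate:
    """OLS rate through tip positions over the longest growth interval."""
    times_s, tips_um = tip_positions(kymo, threshold_frac=threshold_frac)
    idx = _longest_nondecreasing(times_s, tips_um,
                                 monotone_tol_px * kymo.pixel_size_um)
    if len(idx) < 3:
        raise ValueError(
            f"only {len(idx)} valid tip positions; need >= 3 for a rate")
    fit = stats.linregress(times_s[idx], tips_um[idx])
    rate = fit.slope * 60.0
    return GrowthRateEstimate(
        rate_um_min=rate,
        intercept_um=fit.intercept,
        r_squared=float(fit.rvalue**2) if len(idx) > 2 else 1.0,
        n_frames_used=int(len(idx)),
        method="kymograph_tip",
        shrinkage_flag=rate < 0,
    )


def growth_rate_from_lengths(times_s, lengths_um,
                             monotone_tol_um: float = 0.5) -> GrowthRateEstimate:
    """Least-squares slope of length vs time, in um/min.

    A series that shrinks by more than ``monotone_tol_um`` anywhere triggers
    a warning (the fit is still returned); the slope is invariant to a
    uniform time shift.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(lengths_um, dtype=float)
    keep = ~(np.isnan(t) | np.isnan(y))
    t, y = t[keep], y[keep]
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    drops = np.diff(y)
    if np.any(drops < -monotone_tol_um):
        warnings.warn("length series is non-monotone beyond tolerance; "
                      "fit returned anyway", stacklevel=2)
    if np.ptp(y) == 0:
        return GrowthRateEstimate(0.0, float(y[0]), 1.0, len(t),
                                  "length_series")
    fit = stats.linregress(t, y)
    rate = fit.slope * 60.0
    return GrowthRateEstimate(
        rate_um_min=rate,
        intercept_um=fit.intercept,
        r_squared=float(fit.rvalue**2),
        n_frames_used=int(len(t)),
        method="length_series",
        shrinkage_flag=rate < 0,
    )
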
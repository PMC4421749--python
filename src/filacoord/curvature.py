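"""Turning-angle curvature of traced filament segments.

The statistic: along a traced line, take points a fixed arc spacing apart
(10 px at the reference pixel pitch), sum the absolute turning (exterior)
angles at each interior point, and divide by the traced line's length. A
straight line scores exactly zero; a circle of radius R scores
``(180/pi) / R`` degree.um^-1 for equal-arc chords. Angles are reported in
degrees and lengths in micrometres, so the unit is degree.um^-1.

Closed paths (first point == last point within tolerance) are handled
cyclically: every sampled point contributes an angle and the length is the
full perimeter, which makes the circle oracle exact rather than short by
the two open endpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imgseg import extract_segments, skeletonize_mask

logger = logging.getLogger(__name__)


@dataclass
class CurvatureSample:
    segment_id: int
    curvature: float  # degree.um^-1, >= 0
    length_um: float
    n_angle_points: int
    frame_index: int = 0


@dataclass
class CurvatureResult:
    condition: str
    samples: list
    median: float
    percentiles: dict  # keys 5, 25, 75, 95
    n_rejected: int = 0

    def values(self) -> np.ndarray:
        return np.array([s.curvature for s in self.samples])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.condition,
            "segment_id": [s.segment_id for s in self.samples],
            "frame": [s.frame_index for s in self.samples],
            "length_um": [s.length_um for s in self.samples],
            "n_angle_points": [s.n_angle_points for s in self.samples],
            "curvature_deg_per_um": [s.curvature for s in self.samples],
        })

    def summary(self) -> dict:
        """Box-plot summary mirroring a median + 5/25/75/95-percentile plot."""
        return {
            "condition": self.condition,
            "n": len(self.samples),
            "median": self.median,
            "percentiles": self.percentiles,
            "n_rejected": self.n_rejected,
        }


def resample_path(path, step_px: float = 1.0,
                  smooth_sigma_px: float = 0.0) -> np.ndarray:
    """Arc-length parameterized linear interpolation at uniform spacing.

    Endpoints are preserved. Optional Gaussian smoothing of the coordinates
    (before resampling) suppresses pixel-quantization staircase — the
    automated stand-in for tracing by hand and interpolating.
    """
    pts = np.asarray(path, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("path must contain at least two points")
    if smooth_sigma_px > 0:
        pts = ndi.gaussian_filter1d(pts, smooth_sigma_px, axis=0,
                                    mode="nearest")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    total = arc[-1]
    if total == 0:
        raise ValueError("degenerate path: zero length")
    targets = np.arange(0.0, total, step_px)
    if total - targets[-1] > 1e-9:
        targets = np.append(targets, total)
    out = np.column_stack([np.interp(targets, arc, pts[:, i])
                           for i in range(pts.shape[1])])
    return out


class SegmentTooShortError(ValueError):
    """The path cannot accommodate a single angle triple at this spacing."""


def segment_curvature(points, spacing_px: int = 10,
                      pixel_size_um: float = 1.0, segment_id: int = 0,
                      frame_index: int = 0,
                      closed_tol_px: float = 1e-6) -> CurvatureSample:
    """Summed turning angles of points ``spacing_px`` apart over line length.

    ``points`` are resampled pixel coordinates (see :func:`resample_path`).
    Angles are absolute exterior angles between consecutive chords, in
    degrees; the divisor is the traced line's length in um.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise SegmentTooShortError("need at least two points")
    closed = np.linalg.norm(pts[0] - pts[-1]) <= closed_tol_px and len(pts) > 3

    length_px = float(
        np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    if closed:
        pts = pts[:-1]
    sampled = pts[::spacing_px]
    if closed:
        if len(sampled) < 3:
            raise SegmentTooShortError(
                f"closed path too short for spacing {spacing_px}")
        chords = np.diff(np.vstack([sampled, sampled[:1]]), axis=0)
        v1 = chords
        v2 = np.roll(chords, -1, axis=0)
    else:
        if len(sampled) < 3:
            raise SegmentTooShortError(
                f"path too short for one angle triple at spacing {spacing_px}"
            )
        chords = np.diff(sampled, axis=0)
        v1 = chords[:-1]
        v2 = chords[1:]
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = np.einsum("ij,ij->i", v1, v2)
    angles_deg = np.degrees(np.arctan2(np.abs(cross), dot))
    length_um = length_px * pixel_size_um
    return CurvatureSample(
        segment_id=segment_id,
        curvature=float(angles_deg.sum() / length_um),
        length_um=length_um,
        n_angle_points=len(angles_deg),
        frame_index=frame_index,
    )


def aggregate(samples, condition: str = "",
              n_rejected: int = 0) -> CurvatureResult:
    vals = np.array([s.curvature for s in samples])
    if len(vals):
        median = float(np.median(vals))
        pct = {q: float(np.percentile(vals, q)) for q in (5, 25, 75, 95)}
    else:
        median = float("nan")
        pct = {q: float("nan") for q in (5, 25, 75, 95)}
    return CurvatureResult(condition, list(samples), median, pct, n_rejected)


def network_curvature(actin_masks, pixel_size_um: float | None = None,
                      condition: str = "", spacing_px: int = 10,
                      min_length_px: int = 30,
                      smooth_sigma_px: float = 2.0) -> CurvatureResult:
    """Skeletonize -> extract segments -> resample -> per-segment curvature.

    ``smooth_sigma_px`` (default 2) smooths the skeleton path before
    resampling so pixel staircase does not masquerade as curvature; set 0 to
    measure the raw chain. Segments too short for an angle triple are
    excluded and counted in ``n_rejected``.
    """
    samples = []
    n_rejected = 0
    seg_counter = 0
    for t, mask in enumerate(actin_masks):
        px_um = pixel_size_um
        if px_um is None:
            px_um = getattr(mask, "pixel_size_um", 1.0)
        skel = skeletonize_mask(mask)
        for seg in extract_segments(skel, min_length_px=min_length_px,
                                    frame_index=t):
            try:
                pts = resample_path(seg.coords, step_px=1.0,
                                    smooth_sigma_px=smooth_sigma_px)
                samples.append(
                    segment_curvature(pts, spacing_px=spacing_px,
                                      pixel_size_um=px_um,
                                      segment_id=seg_counter,
                                      frame_index=t))
            except (SegmentTooShortError, ValueError):
                n_rejected += 1
            seg_counter += 1
    if n_rejected:
        logger.info("network_curvature: %d segment(s) too short, excluded",
                    n_rejected)
    if not samples:
        logger.warning("network_curvature: no segment passed the filters")
    return aggregate(samples, condition=condition, n_rejected=n_rejected)
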
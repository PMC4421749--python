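"""Microtubule/actin co-alignment: the fraction of the microtubule network
surface co-localizing with F-actin, tracked against total network surface.

The statistic is microtubule-referenced by construction — percent of
microtubule mask pixels also present in the actin mask — and is raw pixel
intersection with no dilation tolerance by default (an optional dilation
radius is provided for PSF-matched analyses). With independent networks it
sits at chance level, i.e. near the actin coverage fraction of the field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imgseg import BinaryMask


def _pixels(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.pixels
    return np.asarray(mask, dtype=bool)


def _pixel_size(mask, default=1.0) -> float:
    return mask.pixel_size_um if isinstance(mask, BinaryMask) else default


@dataclass
class OverlapPoint:
    frame_index: int
    mt_surface_px: int
    mt_surface_um2: float
    percent_coaligned: float  # NaN when the microtubule mask is empty

    @property
    def defined(self) -> bool:
        return not np.isnan(self.percent_coaligned)


@dataclass
class OverlapCurve:
    points: list
    condition: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": [p.frame_index for p in self.points],
            "mt_surface_px": [p.mt_surface_px for p in self.points],
            "mt_surface_um2": [p.mt_surface_um2 for p in self.points],
            "percent_coaligned": [p.percent_coaligned for p in self.points],
            "condition": self.condition,
        })

    def sorted_by_surface(self) -> pd.DataFrame:
        """Plot-ready variant: percent co-aligned vs network surface."""
        return (self.to_dataframe()
                .sort_values("mt_surface_px", kind="stable")
                .reset_index(drop=True))

    def defined_percents(self) -> np.ndarray:
        return np.array([p.percent_coaligned for p in self.points
                         if p.defined])

    def network_percents(self, min_mt_surface_px: int = 300) -> np.ndarray:
        """Per-frame percents restricted to frames with an established
        microtubule network (surface >= ``min_mt_surface_px``).

        The ratio on a near-empty network (a handful of just-detected
        pixels) is estimator noise — a single chance crossing can dominate
        the denominator — so network-level statements are made on frames
        above this floor, the curve-vs-surface analogue of comparing
        conditions at similar network densities.
        """
        return np.array([p.percent_coaligned for p in self.points
                         if p.defined
                         and p.mt_surface_px >= min_mt_surface_px])


def overlap_fraction(mt_mask, actin_mask, dilation_px: int = 0) -> float:
    """Percent of microtubule mask pixels covered by the actin mask.

    Returns NaN (flagged undefined) for an empty microtubule mask; raises on
    shape mismatch. ``dilation_px`` optionally dilates the actin mask first.
    """
    mt = _pixels(mt_mask)
    actin = _pixels(actin_mask)
    if mt.shape != actin.shape:
        raise ValueError(
            f"mask shapes differ: {mt.shape} vs {actin.shape}")
    if dilation_px > 0:
        actin = ndi.binary_dilation(
            actin, structure=ndi.generate_binary_structure(2, 2),
            iterations=dilation_px)
    n_mt = int(np.count_nonzero(mt))
    if n_mt == 0:
        return float("nan")
    n_both = int(np.count_nonzero(mt & actin))
    return 100.0 * n_both / n_mt


def overlap_curve(mt_masks, actin_masks, condition: str = "",
                  dilation_px: int = 0) -> OverlapCurve:
    """One OverlapPoint per frame of an equal-length mask series."""
    mt_masks = list(mt_masks)
    actin_masks = list(actin_masks)
    if len(mt_masks) != len(actin_masks):
        raise ValueError("mask series lengths differ")
    points = []
    for t, (m, a) in enumerate(zip(mt_masks, actin_masks)):
        px_um = _pixel_size(m)
        mt_px = int(np.count_nonzero(_pixels(m)))
        pct = overlap_fraction(m, a, dilation_px=dilation_px)
        points.append(OverlapPoint(t, mt_px, mt_px * px_um**2, pct))
    return OverlapCurve(points, condition=condition)


def match_density_compare(curves, density_window) -> pd.DataFrame:
    """Per-condition co-alignment samples at similar microtubule densities.

    ``density_window`` is an inclusive (lo, hi) window on ``mt_surface_px``.
    Conditions with no frame in the window are excluded with a warning. The
    long-format table feeds the Kruskal-Wallis / Dunn comparison.
    """
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("need at least two curves to compare")
    lo, hi = density_window
    rows = []
    for curve in curves:
        sel = [p for p in curve.points
               if p.defined and lo <= p.mt_surface_px <= hi]
        if not sel:
            warnings.warn(
                f"condition {curve.condition!r}: no frame with mt_surface_px "
                f"in [{lo}, {hi}]; excluded", stacklevel=2)
            continue
        for p in sel:
            rows.append((curve.condition, p.frame_index, p.mt_surface_px,
                         p.percent_coaligned))
    return pd.DataFrame(
        rows, columns=["condition", "frame", "mt_surface_px",
                       "percent_coaligned"])
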
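"""Image-stack container and TIFF / CSV / JSON readers and writers."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A single-channel time-lapse: (T, H, W) intensities with units attached."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be (T, H, W)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.data.shape[1:]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


def write_stack(path, stack: ImageStack) -> None:
    """Write an ImageJ-compatible multi-frame TIFF (um pixel size, s interval)."""
    res = 1.0 / stack.pixel_size_um
    tifffile.imwrite(
        str(path),
        np.asarray(stack.data, dtype=np.float32),
        imagej=True,
        resolution=(res, res),
        metadata={
            "unit": "um",
            "finterval": stack.frame_interval_s,
            "axes": "TYX",
        },
    )


def read_stack(path, channel: str = "") -> ImageStack:
    """Read a multi-frame TIFF written by :func:`write_stack` (or ImageJ)."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        pixel_size_um = 1.0
        frame_interval_s = 1.0
        try:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            if xres is not None:
                num, den = xres.value
                if num:
                    pixel_size_um = den / num
        except (KeyError, AttributeError, ZeroDivisionError):
            pass
        meta = tf.imagej_metadata or {}
        frame_interval_s = float(meta.get("finterval", frame_interval_s))
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data, pixel_size_um, frame_interval_s, channel=channel)


def write_label_stack(path, masks: np.ndarray, pixel_size_um: float,
                      frame_interval_s: float) -> None:
    """Write boolean per-frame label masks as an 8-bit TIFF (0/255)."""
    arr = (np.asarray(masks, dtype=bool).astype(np.uint8)) * 255
    write_stack(path, ImageStack(arr, pixel_size_um, frame_interval_s))


def write_ground_truth_json(path, gt) -> None:
    """Serialize generator filament paths (vertices in um) plus the config."""
    payload = {
        "config": gt.config.to_dict(),
        "paths": [
            {
                "channel": p.channel,
                "birth_time_s": p.birth_time_s,
                "growth_rate_um_min": p.growth_rate_um_min,
                "persistence_um": p.persistence_um,
                "stopped_at_boundary": bool(p.stopped),
                "vertices_um": np.asarray(p.vertices).round(5).tolist(),
                "zipped": np.asarray(p.zipped, dtype=bool).astype(int).tolist(),
                "zip_events": [
                    {
                        "host_index": e.host_index,
                        "self_start": e.self_start,
                        "self_end": e.self_end,
                        "host_start": e.host_start,
                    }
                    for e in p.zip_events
                ],
                "frame_vertex_counts": np.asarray(p.frame_counts).tolist(),
            }
            for p in gt.paths
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
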
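"""Ground-truthed synthetic inputs: filament scenes rendered to dual-channel
movies, and saturation-binding / bundling datasets.

The scene generator is a 2-D worm-like chain with tip growth. Each filament
is a polyline with vertices spaced one pixel apart; per step the tangent
angle diffuses with variance ``ds / Lp`` (the discrete worm-like chain, so
the persistence length directly controls the curvature statistic measured
downstream). Tau-like zippering is modelled geometrically: a growing actin
tip within the capture radius of a microtubule path adopts, with the
configured probability, the host path's vertices from that arc length
onward. Growth rates are never altered by zipping — co-alignment changes
only the geometry, not the kinetics, of the growing polymer.

All randomness flows from ``SceneConfig.seed`` through a fixed
``numpy.random.SeedSequence`` split: child 0 drives the scene (nucleation
and angular diffusion), child 1 drives the renderer (shot and read noise).
Identical configs therefore give bit-identical ground truth and movies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.draw import line as draw_line

from .config import NoiseModel, SceneConfig
from .io import ImageStack

CHANNEL_MT = "microtubule"
CHANNEL_ACTIN = "actin"


@dataclass
class ZipEvent:
    """A contiguous stretch of an actin path that follows a host path."""

    host_index: int
    self_start: int
    self_end: int  # exclusive vertex index on the zipped path
    host_start: int


@dataclass
class FilamentPath:
    channel: str
    birth_time_s: float
    growth_rate_um_min: float
    persistence_um: float
    vertices: np.ndarray = dc_field(default_factory=lambda: np.empty((0, 2)))
    zipped: np.ndarray = dc_field(default_factory=lambda: np.empty(0, bool))
    zip_events: list = dc_field(default_factory=list)
    stopped: bool = False
    frame_counts: np.ndarray = dc_field(default_factory=lambda: np.empty(0, int))

    def length_um(self, ds: float, frame: int | None = None) -> float:
        n = len(self.vertices) if frame is None else int(self.frame_counts[frame])
        return max(0, n - 1) * ds

    def vertices_at(self, frame: int) -> np.ndarray:
        return self.vertices[: int(self.frame_counts[frame])]


@dataclass
class GroundTruth:
    """Per-frame filament states and exact (pre-PSF, pre-noise) label masks."""

    paths: list
    mt_masks: np.ndarray      # (T, H, W) bool
    actin_masks: np.ndarray   # (T, H, W) bool
    config: SceneConfig

    @property
    def n_frames(self) -> int:
        return self.mt_masks.shape[0]

    def masks(self, channel: str) -> np.ndarray:
        if channel == CHANNEL_MT:
            return self.mt_masks
        if channel == CHANNEL_ACTIN:
            return self.actin_masks
        raise ValueError(f"unknown channel {channel!r}")

    def channel_paths(self, channel: str) -> list:
        return [p for p in self.paths if p.channel == channel]

    def zipped_arc_fraction(self) -> float:
        """Fraction of total actin arc length laid down while zipped."""
        steps = zipped = 0
        for p in self.channel_paths(CHANNEL_ACTIN):
            if len(p.vertices) > 1:
                steps += len(p.vertices) - 1
                zipped += int(np.count_nonzero(p.zipped[1:]))
        return zipped / steps if steps else 0.0


class _Grower:
    """Mutable per-filament growth state (tip direction, zip bookkeeping)."""

    __slots__ = ("path", "direction", "verts", "zipped", "zip_state", "carry")

    def __init__(self, path: FilamentPath, direction: float):
        self.path = path
        self.direction = direction
        self.verts: list = []
        self.zipped: list = []
        self.zip_state = None  # (host_index, host_vertex_index, sign, self_start, host_start)


def _target_steps(rate_um_min: float, t: float, birth: float, ds: float) -> int:
    if t < birth:
        return -1  # not yet nucleated (no vertices at all)
    target_len = rate_um_min / 60.0 * (t - birth)
    return int(math.floor(target_len / ds + 1e-9))


def simulate_scene(config: SceneConfig) -> GroundTruth:
    """Grow all filaments frame by frame and rasterize exact label masks.

    Raises ``ValueError`` if the field cannot hold the requested filaments;
    a zero-duration scene yields single-frame ground truth.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])

    ds = config.pixel_size_um
    field = config.field_size_um
    size = config.size_px
    n_frames = config.n_frames
    dt = config.frame_interval_s
    lo = config.nucleation_margin_um
    hi = field - config.nucleation_margin_um

    growers: list[_Grower] = []
    for channel, n, rate, lp, birth in (
        (CHANNEL_MT, config.n_microtubules, config.mt_growth_um_min,
         config.mt_persistence_um, 0.0),
        (CHANNEL_ACTIN, config.n_actin, config.actin_growth_um_min,
         config.actin_persistence_um, config.actin_birth_time_s),
    ):
        for _ in range(n):
            pos = rng.uniform(lo, hi, size=2)
            ang = rng.uniform(0.0, 2.0 * math.pi)
            g = _Grower(FilamentPath(channel, birth, rate, lp), ang)
            g.carry = pos  # nucleation site, placed at birth
            growers.append(g)

    mt_idx = [i for i, g in enumerate(growers) if g.path.channel == CHANNEL_MT]
    act_idx = [i for i, g in enumerate(growers) if g.path.channel == CHANNEL_ACTIN]

    frame_counts = np.zeros((len(growers), n_frames), dtype=int)
    mt_masks = np.zeros((n_frames, size, size), dtype=bool)
    actin_masks = np.zeros((n_frames, size, size), dtype=bool)
    run_mt = np.zeros((size, size), dtype=bool)
    run_act = np.zeros((size, size), dtype=bool)
    drawn_upto = np.zeros(len(growers), dtype=int)

    def wlc_step(g: _Grower) -> bool:
        sigma = math.sqrt(ds / g.path.persistence_um)
        g.direction += rng.normal(0.0, sigma)
        tip = g.verts[-1]
        new = (tip[0] + ds * math.cos(g.direction),
               tip[1] + ds * math.sin(g.direction))
        if not (0.0 <= new[0] < field and 0.0 <= new[1] < field):
            g.path.stopped = True
            return False
        g.verts.append(new)
        g.zipped.append(False)
        return True

    def close_zip(g: _Grower) -> None:
        host, _vidx, _sign, self_start, host_start = g.zip_state
        g.path.zip_events.append(
            ZipEvent(host, self_start, len(g.verts), host_start))
        g.zip_state = None

    def try_zip(g: _Grower, tree, ids, prob: float, exclude_self: int | None):
        """Attach to the nearest capturable host vertex within the radius.

        A candidate with no vertex ahead along the growth direction (the
        host's very end) cannot guide growth and is skipped, which lets a
        tip at one track's end lock onto a neighbouring track instead.
        """
        if tree is None or prob <= 0.0:
            return False
        tip = g.verts[-1]
        dist, j = tree.query(tip, k=8)
        dist = np.atleast_1d(dist)
        j = np.atleast_1d(j)
        dvec = (math.cos(g.direction), math.sin(g.direction))
        for d, jj in zip(dist, j):
            if not np.isfinite(d) or d > config.capture_radius_um:
                break
            host_i, vidx = ids[int(jj)]
            if exclude_self is not None and host_i == exclude_self:
                continue
            hverts = growers[host_i].verts
            a = hverts[min(vidx + 1, len(hverts) - 1)]
            b = hverts[max(vidx - 1, 0)]
            tang = (a[0] - b[0], a[1] - b[1])
            sign = 1 if tang[0] * dvec[0] + tang[1] * dvec[1] >= 0 else -1
            if not 0 <= vidx + sign < len(hverts):
                continue  # no runway: skip sterile end-of-track capture
            if rng.random() >= prob:
                return False
            g.zip_state = (host_i, vidx, sign, len(g.verts), vidx)
            return True
        return False

    def zipped_step(g: _Grower) -> bool:
        """Advance one vertex along the host; fall back to WLC at host ends."""
        host_i, vidx, sign, self_start, host_start = g.zip_state
        nxt = vidx + sign
        hverts = growers[host_i].verts
        if 0 <= nxt < len(hverts):
            tip = g.verts[-1]
            new = hverts[nxt]
            if new[0] != tip[0] or new[1] != tip[1]:
                g.direction = math.atan2(new[1] - tip[1], new[0] - tip[0])
            g.verts.append(tuple(new))
            g.zipped.append(True)
            g.zip_state = (host_i, nxt, sign, self_start, host_start)
            return True
        close_zip(g)
        return wlc_step(g)

    def collect(indices, exclude=None):
        pts, ids = [], []
        for i in indices:
            for v_i, v in enumerate(growers[i].verts):
                pts.append(v)
                ids.append((i, v_i))
        if not pts:
            return None, ids
        return cKDTree(np.asarray(pts)), ids

    for ti in range(n_frames):
        t = ti * dt
        # microtubules first, so actin can zip onto this frame's tracks
        for i in mt_idx:
            g = growers[i]
            n_steps = _target_steps(g.path.growth_rate_um_min, t,
                                    g.path.birth_time_s, ds)
            if n_steps < 0:
                continue
            if not g.verts:
                g.verts.append(tuple(g.carry))
                g.zipped.append(False)
            while not g.path.stopped and len(g.verts) - 1 < n_steps:
                if not wlc_step(g):
                    break

        mt_tree, mt_ids = collect(mt_idx)
        act_tree, act_ids = collect(act_idx)

        for i in act_idx:
            g = growers[i]
            n_steps = _target_steps(g.path.growth_rate_um_min, t,
                                    g.path.birth_time_s, ds)
            if n_steps < 0:
                continue
            if not g.verts:
                g.verts.append(tuple(g.carry))
                g.zipped.append(False)
            while not g.path.stopped and len(g.verts) - 1 < n_steps:
                if g.zip_state is not None:
                    if not zipped_step(g):
                        break
                    continue
                if try_zip(g, mt_tree, mt_ids, config.zip_probability, None):
                    continue
                if try_zip(g, act_tree, act_ids,
                           config.actin_bundle_probability, exclude_self=i):
                    continue
                if not wlc_step(g):
                    break

        # rasterize the increments since the previous frame
        for i, g in enumerate(growers):
            n_now = len(g.verts)
            frame_counts[i, ti] = n_now
            if n_now == 0:
                continue
            run = run_mt if g.path.channel == CHANNEL_MT else run_act
            start = max(drawn_upto[i] - 1, 0)
            if drawn_upto[i] == 0 and n_now >= 1:
                r, c = _px(g.verts[0], ds, size)
                run[r, c] = True
            for vi in range(max(start, 0), n_now - 1):
                r0, c0 = _px(g.verts[vi], ds, size)
                r1, c1 = _px(g.verts[vi + 1], ds, size)
                rr, cc = draw_line(r0, c0, r1, c1)
                run[rr, cc] = True
            drawn_upto[i] = n_now
        mt_masks[ti] = run_mt
        actin_masks[ti] = run_act

    paths = []
    for i, g in enumerate(growers):
        if g.zip_state is not None:
            close_zip(g)
        p = g.path
        p.vertices = np.asarray(g.verts, dtype=float).reshape(-1, 2)
        p.zipped = np.asarray(g.zipped, dtype=bool)
        p.frame_counts = frame_counts[i]
        paths.append(p)
    return GroundTruth(paths, mt_masks, actin_masks, config)


def _px(v, ds: float, size: int) -> tuple:
    r = min(max(int(v[0] / ds), 0), size - 1)
    c = min(max(int(v[1] / ds), 0), size - 1)
    return r, c


def render_movie(gt: GroundTruth, config: SceneConfig | None = None):
    """Rasterized labels -> PSF blur -> scale -> Poisson + read noise.

    Returns ``(microtubule_stack, actin_stack)`` with metadata from the
    config; seeded (SeedSequence child 1 of the scene seed) and reproducible.
    """
    cfg = config if config is not None else gt.config
    if cfg.psf_sigma_um < cfg.pixel_size_um / 2.0:
        warnings.warn("psf_sigma_um < pixel_size_um / 2: undersampled PSF",
                      stacklevel=2)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    nm = cfg.noise_model
    sigma_px = cfg.psf_sigma_px

    stacks = []
    for channel in (CHANNEL_MT, CHANNEL_ACTIN):
        masks = gt.masks(channel)
        out = np.empty(masks.shape, dtype=np.float32)
        for t in range(masks.shape[0]):
            lam = nm.background + nm.signal * gaussian_filter(
                masks[t].astype(np.float64), sigma_px)
            img = rng.poisson(lam * nm.gain) / nm.gain
            img = img + rng.normal(0.0, nm.read_noise_sd, size=lam.shape)
            out[t] = img.astype(np.float32)
        stacks.append(ImageStack(out, cfg.pixel_size_um, cfg.frame_interval_s,
                                 channel=channel))
    return stacks[0], stacks[1]


# ---------------------------------------------------------------------------
# Biochemistry dataset simulators
# ---------------------------------------------------------------------------

@dataclass
class BindingDataset:
    """Saturation-binding replicate: % of tau pelleted vs polymer concentration."""

    polymer_concentration_uM: np.ndarray
    fraction_bound_pct: np.ndarray
    replicate_id: int = 0
    seed: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "concentration_uM": self.polymer_concentration_uM,
            "fraction_bound_pct": self.fraction_bound_pct,
            "replicate": self.replicate_id,
        })


@dataclass
class BundlingDataset:
    """Low-speed-sedimentation bundling: % actin pelleted vs tau concentration."""

    tau_concentration_uM: np.ndarray
    pellet_fraction_pct: np.ndarray
    seed: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "concentration_uM": self.tau_concentration_uM,
            "fraction_bound_pct": self.pellet_fraction_pct,
            "replicate": 0,
        })


def _check_concentrations(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if c.ndim != 1 or len(c) == 0:
        raise ValueError("concentrations must be a non-empty 1-D array")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if np.any(np.diff(c) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    if not np.any(c > 0):
        raise ValueError("all concentrations are zero: Kd unidentifiable")
    return c


def simulate_binding(kd_nM: float, bmax_pct: float, concentrations_uM,
                     noise_sd_pct: float, n_replicates: int,
                     seed: int) -> list:
    """Hyperbolic saturation binding plus Gaussian noise, clipped to [0, 100].

    ``fraction = bmax * c / (kd + c) + eps``; ``kd`` is given in nM and
    converted to uM internally to match the concentration axis.
    """
    if kd_nM <= 0:
        raise ValueError("kd_nM must be > 0")
    if not 0 < bmax_pct <= 100:
        raise ValueError("bmax_pct must lie in (0, 100]")
    c = _check_concentrations(concentrations_uM)
    kd_uM = kd_nM / 1000.0
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(n_replicates):
        y = bmax_pct * c / (kd_uM + c)
        if noise_sd_pct > 0:
            y = y + rng.normal(0.0, noise_sd_pct, size=len(c))
        out.append(BindingDataset(c.copy(), np.clip(y, 0.0, 100.0),
                                  replicate_id=rep, seed=seed))
    return out


def simulate_bundling(ec50_uM: float, max_pellet_pct: float,
                      tau_concentrations_uM, noise_sd_pct: float,
                      seed: int) -> BundlingDataset:
    """Saturating (hyperbolic) pelleted-bundle fraction vs tau concentration."""
    if ec50_uM <= 0:
        raise ValueError("ec50_uM must be > 0")
    c = np.asarray(tau_concentrations_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("tau concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    y = max_pellet_pct * c / (ec50_uM + c)
    if noise_sd_pct > 0:
        y = y + rng.normal(0.0, noise_sd_pct, size=len(c))
    return BundlingDataset(c, np.clip(y, 0.0, 100.0), seed=seed)
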
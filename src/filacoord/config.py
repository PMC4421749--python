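"""Scene and noise configuration for the synthetic TIRF generator.

All spatial quantities are in micrometres, times in seconds, growth rates in
um/min (the units used on TIRF microscope acquisition software and in the
downstream statistics). The defaults encode the acquisition geometry of a
standard EMCCD TIRF setup: 16 um camera pixels behind a 60X objective
(16/60 = 0.267 um/px) and one frame every 5 s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import yaml

#: Default pixel pitch, um/px (16 um camera pixel / 60X objective).
DEFAULT_PIXEL_SIZE_UM = 16.0 / 60.0

#: Default frame interval, s.
DEFAULT_FRAME_INTERVAL_S = 5.0


@dataclass
class NoiseModel:
    """EMCCD-style noise: Poisson shot noise on (background + signal) plus
    additive Gaussian read noise.

    Parameters
    ----------
    background : float
        Mean background level, counts.
    read_noise_sd : float
        Gaussian read-noise standard deviation, counts.
    gain : float
        Poisson gain (events per count); the Poisson draw is taken on
        ``gain * lambda`` and rescaled, so ``gain`` > 1 reduces shot noise.
    signal : float
        Pre-blur line intensity of a filament, counts. A 1-px-wide filament
        blurred by the PSF peaks at ``signal * erf(0.5 / (sigma_px * sqrt 2))``.
    """

    background: float = 20.0
    read_noise_sd: float = 2.0
    gain: float = 1.0
    signal: float = 400.0

    @classmethod
    def for_snr(
        cls,
        snr: float,
        psf_sigma_px: float,
        background: float = 20.0,
        read_noise_sd: float = 2.0,
        gain: float = 1.0,
    ) -> "NoiseModel":
        """Choose the line intensity so the post-blur peak over the noise SD
        at the peak equals ``snr``.

        Solves ``peak = snr * sqrt(background + peak + read_noise_sd**2)``
        for the peak and divides by the PSF attenuation of a 1-px line.
        """
        var0 = background + read_noise_sd**2
        peak = 0.5 * (snr**2 + math.sqrt(snr**4 + 4.0 * snr**2 * var0))
        atten = math.erf(0.5 / (psf_sigma_px * math.sqrt(2.0)))
        return cls(background, read_noise_sd, gain, signal=peak / atten)


@dataclass
class SceneConfig:
    """Parameters of one synthetic dual-channel filament scene.

    Filaments nucleate at seeded random positions/orientations inside a
    margin and grow from their tip in steps of one pixel, with worm-like-chain
    angular diffusion set by the persistence length. A growing actin tip that
    passes within ``capture_radius_um`` of a microtubule path can zipper onto
    it (tau-like cross-linking); ``actin_bundle_probability`` does the same
    between actin filaments (fascin-like bundling). Zippering changes only
    the geometry of the growing filament, never its growth rate.
    """

    field_size_um: float = 68.352          # 256 px at the default pixel pitch
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    duration_s: float = 600.0
    n_microtubules: int = 8
    n_actin: int = 12
    mt_growth_um_min: float = 1.28
    actin_growth_um_min: float = 1.78
    mt_persistence_um: float = 2000.0      # microtubules are mm-stiff
    actin_persistence_um: float = 10.0     # F-actin Lp ~ 10 um
    zip_probability: float = 0.0
    capture_radius_um: float = 0.5
    actin_bundle_probability: float = 0.0
    psf_sigma_um: float = 0.30
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    nucleation_margin_um: float = 5.0
    actin_birth_time_s: float = 0.0
    seed: int = 0

    # -- derived geometry -------------------------------------------------
    @property
    def size_px(self) -> int:
        return int(round(self.field_size_um / self.pixel_size_um))

    @property
    def n_frames(self) -> int:
        return max(1, int(round(self.duration_s / self.frame_interval_s)) + 1)

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_um / self.pixel_size_um

    def validate(self) -> None:
        for name in (
            "field_size_um",
            "pixel_size_um",
            "frame_interval_s",
            "mt_growth_um_min",
            "actin_growth_um_min",
            "mt_persistence_um",
            "actin_persistence_um",
            "capture_radius_um",
            "psf_sigma_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("zip_probability", "actin_bundle_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.duration_s < 0:
            raise ValueError("duration_s must be >= 0")
        if self.n_microtubules < 0 or self.n_actin < 0:
            raise ValueError("filament counts must be >= 0")
        if self.capture_radius_um < self.pixel_size_um:
            warnings.warn(
                "capture_radius_um < pixel_size_um: zip capture is sub-pixel",
                stacklevel=2,
            )
        n_fil = self.n_microtubules + self.n_actin
        if n_fil > 0 and self.field_size_um <= 2 * self.nucleation_margin_um:
            raise ValueError(
                "field too small to place requested filaments: "
                f"field_size_um={self.field_size_um} <= "
                f"2 * nucleation_margin_um={2 * self.nucleation_margin_um}"
            )

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        nm = d.get("noise_model")
        if isinstance(nm, dict):
            d["noise_model"] = NoiseModel(**nm)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
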
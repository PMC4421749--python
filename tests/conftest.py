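import numpy as np
import pytest

from filacoord.config import NoiseModel, SceneConfig

PX = 16.0 / 60.0  # um/px


@pytest.fixture(scope="session")
def px():
    return PX


@pytest.fixture(scope="session")
def single_mt_movie():
    """One straight microtubule growing at 1.28 um/min, SNR 10, rendered."""
    from filacoord.synthgen import render_movie, simulate_scene

    cfg = SceneConfig(
        field_size_um=128 * PX,
        n_microtubules=1,
        n_actin=0,
        mt_growth_um_min=1.28,
        mt_persistence_um=1e5,
        duration_s=400.0,
        nucleation_margin_um=12.0,
        noise_model=NoiseModel.for_snr(10.0, 0.30 / PX),
        seed=2,
    )
    gt = simulate_scene(cfg)
    mt_stack, actin_stack = render_movie(gt)
    return cfg, gt, mt_stack


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
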
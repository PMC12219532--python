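import numpy as np
import pytest

from orgspat.synthetic import SceneConfig, generate_scene


def small_scene_config(seed: int = 0, noise_sd: float = 5.0, **kw) -> SceneConfig:
    """A reduced scene used throughout the suite: same anatomy, smaller canvas.

    Counts and fractions are scaled so objects still clear the default
    size-exclusion thresholds (mito/LD >= 5000 px, ER/glycogen >= 500 px).
    """
    defaults = dict(
        image_shape=(448, 448),
        counts={"mitochondria": 2, "er": 2, "glycogen": 2, "ld": 1},
        area_fractions={
            "nucleus": 0.15,
            "mitochondria": 0.10,
            "er": 0.05,
            "glycogen": 0.04,
            "ld": 0.05,
        },
        noise_sd=noise_sd,
        seed=seed,
    )
    defaults.update(kw)
    return SceneConfig(**defaults)


#: size-exclusion thresholds matched to the reduced scene scale (objects in
#: the 448 px scenes are ~4x smaller in area than at full scale)
SCALED_SIZE_THRESHOLDS = {"er": 125, "mitochondria": 1250, "glycogen": 125, "ld": 1250}


@pytest.fixture(scope="session")
def scene():
    """One deterministic mid-size scene with planted contacts."""
    cfg = small_scene_config(
        seed=11,
        contact_plan=[("mitochondria", "er", 1), ("mitochondria", "ld", 0)],
    )
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def noiseless_scene():
    cfg = small_scene_config(seed=5, noise_sd=0.0)
    return generate_scene(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
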
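import numpy as np
import pytest

from phenospectra import cube, scene


@pytest.fixture(scope="session")
def small_scene():
    """Reduced-size two-sensor scene with shading, glint and gain variation."""
    cfg = scene.SceneConfig(
        lines=192, vnir_samples=144, swir_samples=132,
        vnir_wavelengths=np.linspace(400, 1000, 60),
        swir_wavelengths=np.linspace(970, 2500, 60),
        shade_fraction=0.08, specular_fraction=0.005, leaf_scale_sd=0.02,
    )
    return scene.generate_scene(cfg, seed=2)


@pytest.fixture(scope="session")
def calibrated_small_scene(small_scene):
    vnir, swir, refs_v, refs_s, truth = small_scene
    return (
        cube.calibrate_reflectance(vnir, refs_v),
        cube.calibrate_reflectance(swir, refs_s),
        truth,
    )


@pytest.fixture(scope="session")
def clean_scene():
    """Unit-gain scene without shading/glint: calibration inverts exactly."""
    cfg = scene.SceneConfig(
        lines=64, vnir_samples=48, swir_samples=40,
        vnir_wavelengths=np.linspace(400, 1000, 30),
        swir_wavelengths=np.linspace(970, 2500, 30),
        gain_min=1.0, gain_max=1.0, shade_fraction=0.0,
        specular_fraction=0.0, leaf_scale_sd=0.0,
    )
    return scene.generate_scene(cfg, seed=1)
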
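import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from benthograd.config import default_config
from benthograd.pipeline import build_rasters, build_scenes
from benthograd.raster import classify, distance_to_tracks, rasterize
from benthograd.synthetic import default_community, generate_specimens, make_scene

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(seed=7)


@pytest.fixture(scope="session")
def default_scenes(default_cfg):
    """Desk-scale disturbed (DEA) and reference (REF) scenes."""
    return build_scenes(default_cfg)


@pytest.fixture(scope="session")
def default_rasters(default_cfg, default_scenes):
    """Classified 0.5 m rasters of the two default scenes."""
    return build_rasters(default_cfg, default_scenes)


@pytest.fixture(scope="session")
def ref_1ha():
    """A 1 ha no-track scene and its classified raster (all level D)."""
    scene = make_scene(1.0, 0, seed=2, height=100.0, name="REF1")
    r = classify(distance_to_tracks(rasterize(scene, 0.5), scene.tracks))
    return scene, r


@pytest.fixture(scope="session")
def small_tracked():
    """A 50 x 50 m scene with two 4 m tracks and its classified raster."""
    scene = make_scene(0.25, 2, 4.0, 20.0, seed=3, height=50.0, name="MINI")
    r = classify(distance_to_tracks(rasterize(scene, 0.5), scene.tracks))
    return scene, r


@pytest.fixture(scope="session")
def default_specimens(default_scenes, default_rasters):
    spec = default_community()
    dea, ref = default_scenes
    rd, rr = default_rasters
    return (
        generate_specimens(dea, rd, spec, 101),
        generate_specimens(ref, rr, spec, 102),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20190529)
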
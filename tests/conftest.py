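import numpy as np
import pytest
from skimage import draw

from spherotome.config import RunConfig
from spherotome.phantoms import make_scene
from spherotome.pipeline import run_pipeline
from spherotome.regions import PlanarRegion


def disk_mask(shape, center, radius):
    m = np.zeros(shape, bool)
    m[draw.disk(center, radius, shape=shape)] = True
    return m


def disk_region(shape, center, radius, **kw):
    return PlanarRegion(disk_mask(shape, center, radius), frame_shape=shape, **kw)


@pytest.fixture(scope="session")
def wt_scene():
    """20-cell wild-type scene with ground truth (shared across tests)."""
    bf, nuc, truth, geom, specs = make_scene(20, field_shape=(640, 640), seed=1)
    return dict(bf=bf, nuc=nuc, truth=truth, geom=geom, specs=specs)


@pytest.fixture(scope="session")
def wt_result(wt_scene):
    """Full pipeline run on the wild-type scene.

    Volumetric validation runs without nuclear dilation: the dilation step
    exists to capture peripheral fluorophore signal and deliberately
    inflates the nuclear ROI."""
    cfg = RunConfig(dilation_um=0.0)
    return run_pipeline(wt_scene["bf"], wt_scene["nuc"], config=cfg)
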
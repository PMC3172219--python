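import numpy as np
import pytest

from actinmesh.geometry import CentralRegion, RingGeometry, central_region
from actinmesh.holes import segment_actin
from actinmesh.synth import MeshFixtureSpec, make_mesh_fixture


@pytest.fixture(scope="session")
def fixture18():
    """10x10 µm binary field at 10 nm/px with 18 square holes of side 750 nm."""
    img, truth = make_mesh_fixture(MeshFixtureSpec())
    return img, truth


@pytest.fixture(scope="session")
def full_region():
    """Declared 10x10 µm central region covering the whole fixture field."""
    def make(img):
        return central_region(
            RingGeometry(False), None, img.pixel_size_nm,
            override_mask=np.ones(img.shape, dtype=bool),
        )
    return make


@pytest.fixture(scope="session")
def activated_pipeline():
    """Activated-preset mesh run through segmentation -> central region."""
    from actinmesh.geometry import detect_ring, segment_cell
    from actinmesh.synth import ACTIVATED_PRESET, SimulationSpec, simulate_actin_image

    spec = SimulationSpec(seed=0, **ACTIVATED_PRESET)
    img, truth = simulate_actin_image(spec)
    cell = segment_cell(img)
    ring = detect_ring(img, cell)
    region = central_region(ring, cell, img.pixel_size_nm)
    actin = segment_actin(img, "otsu", region=region)
    return {"img": img, "truth": truth, "cell": cell, "ring": ring,
            "region": region, "actin": actin}
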
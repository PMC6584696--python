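import numpy as np
import pytest

from hvmkit.config import AnalysisConfig
from hvmkit.synthetic import SceneSpec, VesselSpec, render_scene


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def straight_tube_scene():
    """One straight 10-um capillary flowing at 300 um/s, clean optics."""
    spec = SceneSpec(
        width=192, height=192, n_frames=60,
        vessels=[VesselSpec([(20.0, 96.0), (172.0, 96.0)], diameter_um=10.0,
                            velocity_um_s=300.0, cell_spacing_um=20.0)],
        seed=42,
    )
    return render_scene(spec)


@pytest.fixture(scope="session")
def barcode_scene():
    """Static cells in a tube: the no-flow 'barcode' archetype."""
    spec = SceneSpec(
        width=192, height=192, n_frames=60,
        vessels=[VesselSpec([(20.0, 96.0), (172.0, 96.0)], diameter_um=10.0,
                            velocity_um_s=0.0, cell_spacing_um=20.0)],
        seed=43,
    )
    return render_scene(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
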
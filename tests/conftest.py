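import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aquage import ReactorConfig
from aquage.synthetic import Cluster, StackScenario, simulate_zstack

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")


@pytest.fixture
def config():
    """Default reactor configuration (V = 1008 mL, Q = 2.1 mL/min, A = 190 cm^2)."""
    return ReactorConfig()


@pytest.fixture
def small_cluster_stack():
    """One 18 µm hemisphere in a 128 px frame at 1 µm voxels, with shot noise."""
    scn = StackScenario(
        frame_px=128, n_slices=26, pixel_um=1.0, slice_um=1.0,
        clusters=(Cluster(center_um=(64.0, 64.0), radius_um=18.0),),
        seed=2,
    )
    return simulate_zstack(scn), scn


@pytest.fixture
def noise_free_cluster_stack():
    """Same cluster geometry without background noise (exact-truth regime)."""
    scn = StackScenario(
        frame_px=128, n_slices=26, pixel_um=1.0, slice_um=1.0,
        clusters=(Cluster(center_um=(64.0, 64.0), radius_um=18.0),),
        background_density=0.0, seed=2,
    )
    return simulate_zstack(scn), scn
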
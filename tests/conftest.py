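import numpy as np
import pytest
from hypothesis import settings

from dcekin import AcquisitionSpec, AifModelParams, LesionSpec, PhantomScene
from dcekin.phantom import AortaSpec, population_aif

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol() -> AcquisitionSpec:
    """The default 6 + 120 frame acquisition protocol."""
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def aif_params() -> AifModelParams:
    return AifModelParams()


@pytest.fixture(scope="session")
def dynamic_aif(protocol, aif_params) -> np.ndarray:
    return population_aif(protocol.dynamic_times(), aif_params)


@pytest.fixture()
def small_scene() -> PhantomScene:
    """A small noiseless scene: one aorta, two lesions (one with a rim)."""
    acq = AcquisitionSpec(n_dynamic=60)
    return PhantomScene(
        grid_shape=(24, 24, 10),
        acquisition=acq,
        aorta=AortaSpec(centre_xy=(5, 5), radius=2.5),
        lesions=(
            LesionSpec(centre=(16, 8, 5), radius=3.0, ktrans_true=0.8, ecv_true=35.0),
            LesionSpec(
                centre=(8, 17, 5), radius=2.5, ktrans_true=0.4, ecv_true=25.0,
                rim_width=1, rim_scale=0.5, organ_label="liver",
            ),
        ),
        noise_sd=0.0,
        seed=11,
    )
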
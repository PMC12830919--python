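import numpy as np
import pytest

from octavd import SynthConfig, frangi_vesselness, generate_cohort, render_vessel_network
from octavd.binarize import binarize_map
from octavd.synth import Geometry

SIZE = 128
PIXEL_MM = 3.0 / SIZE  # keep a 3 mm field of view at desk-scale resolution


def small_config(**overrides) -> SynthConfig:
    base = dict(image_size_px=SIZE, pixel_size_mm=PIXEL_MM, faz_radius_mm=0.3,
                n_patients=16, two_eye_fraction=0.5, seed=0)
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def geometry() -> Geometry:
    return Geometry(size_px=SIZE, pixel_size_mm=PIXEL_MM, faz_radius_mm=0.3)


@pytest.fixture(scope="session")
def svp_image(geometry):
    return render_vessel_network(geometry, "SVP", np.random.default_rng(42))


@pytest.fixture(scope="session")
def svp_binary(svp_image):
    return binarize_map(frangi_vesselness(svp_image))


@pytest.fixture(scope="session")
def tiny_cohort():
    """16 patients, ~24 eyes, no class effect — for structural tests."""
    return generate_cohort(small_config())
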
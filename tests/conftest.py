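import numpy as np
import pytest

from vesselseg.network import ModelConfig, CollabPatchNet
from vesselseg.patch_engine import PatchGeometry
from vesselseg.preprocessing import preprocess_image
from vesselseg.synthetic import SyntheticVesselSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_geometry():
    return PatchGeometry(s=24, l=48)


@pytest.fixture(scope="session")
def tiny_config(tiny_geometry):
    return ModelConfig(channels=(4, 8), geometry=tiny_geometry)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    model = CollabPatchNet(tiny_config)
    model.eval()
    return model


@pytest.fixture(scope="session")
def synth_record():
    """One 96x96 synthetic fundus-like record with GT/FOV/edges."""
    return generate(SyntheticVesselSpec(image_size=(96, 96), seed=3))


@pytest.fixture(scope="session")
def synth_image(synth_record):
    return preprocess_image(synth_record.image).astype(np.float32)
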
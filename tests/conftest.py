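import numpy as np
import pytest

from thermoscreen.inverse import ForwardOperator
from thermoscreen.phantom import (
    AmbientConditions,
    build_hemisphere_phantom,
    default_tissue_properties,
)


@pytest.fixture(scope="session")
def props():
    return default_tissue_properties()


@pytest.fixture(scope="session")
def ambient():
    return AmbientConditions()


@pytest.fixture(scope="session")
def small_phantom():
    """5 cm breast at 2.5 mm voxels: cheap enough for repeated solves."""
    return build_hemisphere_phantom(0.05, 0.0025, gland_fraction=0.5)


@pytest.fixture(scope="session")
def small_operator(small_phantom, props, ambient):
    """Shared forward operator (assembles and solves the tumor-free base once)."""
    return ForwardOperator(small_phantom, props, ambient)
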
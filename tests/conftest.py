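import numpy as np
import pytest

from epimech.geometry import build_monolayer
from epimech.patchgen import PatchSpec, generate_hex_patch


@pytest.fixture(scope="session")
def rosette_centers():
    """Perfect 7-centre hexagonal rosette (zero noise)."""
    return generate_hex_patch(PatchSpec(n_cells=7, noise_amplitude=0.0, seed=1))


@pytest.fixture(scope="session")
def rosette(rosette_centers):
    return build_monolayer(rosette_centers, height_um=35.0, length_unit_um=40.0)


@pytest.fixture(scope="session")
def patch20_centers():
    return generate_hex_patch(PatchSpec(n_cells=20, noise_amplitude=0.25, seed=3))


@pytest.fixture()
def patch20(patch20_centers):
    return build_monolayer(patch20_centers, height_um=35.0, length_unit_um=40.0)


@pytest.fixture(scope="session")
def patch40_centers():
    return generate_hex_patch(PatchSpec(n_cells=40, noise_amplitude=0.2, seed=7))


@pytest.fixture()
def patch40(patch40_centers):
    return build_monolayer(patch40_centers, height_um=35.0, length_unit_um=40.0)
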
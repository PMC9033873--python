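import numpy as np
import pytest

from brightwell.hill import DoseResponseParams
from brightwell.simulate import (
    BUILTIN_PROFILES,
    CellLineProfile,
    NoiseSpec,
    PlateDesign,
    simulate_plate,
)

# the 11-dose ladder used throughout
DOSES = np.array([0.0001, 0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1, 5, 10, 100])


@pytest.fixture(scope="session")
def small_design():
    """Tiny plate for image-level tests: full dose ladder, small images."""
    return PlateDesign(replicates=2, sets=1, image_height_px=96, image_width_px=112)


@pytest.fixture(scope="session")
def small_plate(small_design, tmp_path_factory):
    """22 rendered wells of lineA at 96x112 px."""
    out = tmp_path_factory.mktemp("plate")
    records = simulate_plate(BUILTIN_PROFILES["lineA"], small_design, out, seed=7)
    return records, out


@pytest.fixture(scope="session")
def labels_only_plate():
    """Full 264-well plate, labels only (no images rendered)."""
    return simulate_plate(
        BUILTIN_PROFILES["lineA"], PlateDesign(), "unused", seed=11,
        write_images=False,
    )


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))
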
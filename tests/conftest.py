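import numpy as np
import pytest

from helixsans.peptide_model import build_topology
from helixsans.synthetic_data import (
    Frame,
    Trajectory,
    generate_ideal_helix,
    generate_random_coil,
)


@pytest.fixture(scope="session")
def model10():
    """10-mer with neutral triazole side-chains (coil state)."""
    return build_topology(10, "triazole", protonated=False)


@pytest.fixture(scope="session")
def model10_protonated():
    """10-mer with every triazole protonated (helical state)."""
    return build_topology(10, "triazole", protonated=True)


@pytest.fixture(scope="session")
def helix10(model10_protonated):
    """Ideal helix at the canonical geometry (0.23 nm, 100 deg, 0.15 nm)."""
    return generate_ideal_helix(10, model=model10_protonated)


@pytest.fixture(scope="session")
def coil10(model10):
    return generate_random_coil(10, seed=3, model=model10)


def vacuum_frame(conf) -> Frame:
    """Frame with no waters in an effectively infinite box."""
    return Frame(conf, np.empty((0, 3)), np.empty((0, 2, 3)), box_edge=1e6)


@pytest.fixture()
def vacuum_helix_frame(helix10):
    return vacuum_frame(helix10)


def single_frame_trajectory(frame) -> Trajectory:
    return Trajectory([frame], time_step_ns=0.1)
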
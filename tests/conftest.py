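import numpy as np
import pytest

from coagclass import toy_model_path
from coagclass.kinetics import (
    Reaction,
    ReactionNetwork,
    SimulationProfile,
    Species,
    parse_model_file,
)

CHAIN_K1 = 1.0e-2
CHAIN_K2 = 5.0e-3
CHAIN_A0 = 1.0e-9


@pytest.fixture()
def chain_network() -> ReactionNetwork:
    """First-order chain A -> B -> C; admits a matrix-exponential solution."""
    return ReactionNetwork(
        [Species("A", CHAIN_A0), Species("B", 0.0), Species("C", 0.0)],
        [
            Reaction({"A": 1}, {"B": 1}, CHAIN_K1),
            Reaction({"B": 1}, {"C": 1}, CHAIN_K2),
        ],
    )


@pytest.fixture(scope="session")
def toy_network() -> ReactionNetwork:
    """The bundled reduced clotting-cascade model."""
    return parse_model_file(toy_model_path())


def make_profile(times, rows: dict[str, np.ndarray]) -> SimulationProfile:
    names = list(rows)
    return SimulationProfile(
        np.asarray(times, float),
        np.vstack([rows[n] for n in names]),
        names,
    )
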
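import logging

import numpy as np
import pytest

from pullgeom import cli_io, synthetic_data as sd

logging.getLogger("MDAnalysis").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tether():
    return sd.default_tether()


@pytest.fixture(scope="session")
def subunit_params():
    return sd._default_subunit_params()


@pytest.fixture(scope="session")
def stage_config():
    return cli_io.TraceStageConfig()


@pytest.fixture(scope="session")
def strong_bond_traces(tether, subunit_params):
    """Noisy traces of the strong pulling geometry (440 pN modal force)."""
    return [
        sd.simulate_trace(tether, subunit_params["D"], sd.AcquisitionProtocol(seed=s))
        for s in range(20)
    ]


@pytest.fixture(scope="session")
def toy_pull():
    """One toy constant-velocity pull replica with its force series."""
    traj, force = sd.generate_smd_pull_trajectory(sd.ToyPullModel(), 1500, seed=11)
    return traj, force


@pytest.fixture(scope="session")
def ring_spec():
    """Eight nodes on a ring with a high-correlation route on one side.

    The short arc (source 0 -> sink 3 via 1, 2) has weak correlation 0.45;
    the long arc (via 7..4) is strongly correlated at 0.93, so the optimal
    force-propagation path takes the long way round.
    """
    n = 8
    C = np.eye(n)
    strong = [(0, 7), (7, 6), (6, 5), (5, 4), (4, 3)]
    weak = [(0, 1), (1, 2), (2, 3)]
    for a, b in strong:
        C[a, b] = C[b, a] = 0.93
    for a, b in weak:
        C[a, b] = C[b, a] = 0.45
    w, V = np.linalg.eigh(C)
    C = (V * np.clip(w, 1e-3, None)) @ V.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    radius = 3.5 / (2 * np.sin(np.pi / n))
    ang = 2 * np.pi * np.arange(n) / n
    pos = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)])
    return sd.CorrelationSpec(
        n_nodes=n, target_correlation=C, mean_positions=pos, fluctuation_sd=0.3
    )
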
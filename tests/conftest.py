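import warnings

import numpy as np
import pytest

from poregate import ChannelSpec, generate_topology, generate_trajectory
from poregate.traj_io import write_pdb


@pytest.fixture(autouse=True)
def _quiet_mdanalysis():
    warnings.filterwarnings("ignore", category=DeprecationWarning)
    yield


@pytest.fixture
def spec():
    return ChannelSpec()


@pytest.fixture
def spec_ions():
    return ChannelSpec(n_ions=10)


@pytest.fixture
def toy_pdb(tmp_path, spec_ions):
    """4-chain, 16-residue/chain toy channel with 10 K+ ions as a PDB file."""
    topo = generate_topology(spec_ions)
    traj, _ = generate_trajectory(spec_ions, n_frames=1)
    path = tmp_path / "toy.pdb"
    write_pdb(topo, traj.coordinates[0], str(path))
    return path


def brute_force_min_distance(coords: np.ndarray, idx_a, idx_b) -> float:
    """Independent O(n^2) scan used as an oracle in several test modules."""
    best = np.inf
    for i in idx_a:
        for j in idx_b:
            d = float(np.linalg.norm(coords[i] - coords[j]))
            best = min(best, d)
    return best
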
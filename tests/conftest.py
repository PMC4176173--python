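import numpy as np
import pytest

from rnapjam.core_model import KineticParams, build_gene


def assert_trajectory_valid(traj, gene=None, d=None):
    """Conservation, exclusion and stalled-on-pause-site invariants."""
    gene = gene or traj.gene
    d = d or traj.params.footprint
    assert np.all(traj.initiated - traj.completed == traj.on_lattice), "conservation violated"
    assert np.all(np.diff(traj.completed) >= 0)
    assert np.all(np.diff(traj.initiated) >= 0)
    if traj.snapshot_positions is not None:
        pause = set(gene.pause_sites)
        for i in range(traj.n_snapshots):
            pos, states = traj.snapshot(i)
            assert pos.size == traj.on_lattice[i]
            assert np.all((pos >= 1) & (pos <= gene.length))
            if pos.size > 1:
                spacing = -np.diff(pos)  # positions are descending
                assert np.all(spacing >= d), f"exclusion violated at snapshot {i}"
            for p, s in zip(pos, states):
                if s == 1:
                    assert int(p) in pause, f"stalled complex off pause site ({p})"


@pytest.fixture(scope="session")
def check_trajectory():
    return assert_trajectory_valid


@pytest.fixture(scope="session")
def pause_gene():
    """100-site gene with 5 pause sites."""
    return build_gene(100, 0.05, seed=3)


@pytest.fixture(scope="session")
def plain_gene():
    """100-site gene without pauses."""
    return build_gene(100, 0.0, seed=0)


@pytest.fixture(scope="session")
def single_complex_params():
    return KineticParams(alpha=0.0, epsilon=50.0, f=0.0, tau=1.0, footprint=35, dt=0.002)
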
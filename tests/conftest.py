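"""Shared fixtures: scaled-down synthetic channels so every stage can be
exercised in seconds.  Session scope amortises the expensive builds."""

import numpy as np
import pytest

from chancav.synthetic import (CavitySpec, ChannelSpec, LigandSpec,
                               build_pentamer, simulate_trajectory)

SPECIES_RULES = {
    "WAL": "protein", "BOD": "protein", "CAV": "protein",
    "ALA": "protein", "ILE": "protein", "PHE": "protein",
    "HOH": "water", "EOH": "ligand", "DOP": "lipid",
}


def fast_spec(**kw) -> ChannelSpec:
    """A coarser, lighter channel for unit tests."""
    defaults = dict(wall_ring_step=1.0, body_lattice=2.0, shell_spacing=0.8,
                    seed=1)
    defaults.update(kw)
    spec = ChannelSpec(**defaults)
    spec.water.bulk_count = 200
    spec.ligand.count = 10
    return spec


@pytest.fixture(scope="session")
def pentamer():
    """Static fast pentamer: (spec, topology, frame, truth)."""
    spec = fast_spec()
    topo, frame, truth = build_pentamer(spec)
    return spec, topo, frame, truth


@pytest.fixture(scope="session")
def small_traj():
    """A 30-frame trajectory of the fast system: (spec, traj, truth)."""
    spec = fast_spec(seed=3)
    spec.ligand = LigandSpec(count=10, tau_bound=20.0, tau_unbound=60.0)
    traj, truth = simulate_trajectory(spec, n_frames=30, dt=1.0, seed=3)
    return spec, traj, truth


@pytest.fixture(scope="session")
def consensus_small(small_traj):
    """Consensus grid + classified cavities of the small trajectory."""
    from chancav.cavities import classify_cavities, consensus_cavities
    from chancav.pore import align_to_pore_axis

    spec, traj, truth = small_traj
    grid, comps = consensus_cavities(traj, stride_ns=10.0)
    ref, _, _ = align_to_pore_axis(traj.frame(0), traj.topology)
    cavities = classify_cavities(comps, ref, traj.topology, grid)
    return grid, comps, cavities, ref


@pytest.fixture(scope="session")
def truth_regions(small_traj):
    """Ground-truth cavity regions (voxel centres) on a 1 Å lattice."""
    from chancav.cavities import VoidGrid

    spec, traj, truth = small_traj
    origin = np.array([-20.0, -20.0, -20.0])
    shape = (40, 40, 36)
    grid = VoidGrid(origin, 1.0, np.zeros(shape, bool))
    regions = {s.cavity_id: grid.centers(s.truth_voxels(origin, 1.0, shape))
               for s in truth.sites}
    return grid, regions
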
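import numpy as np
import pytest

from amdreweigh import (
    SamplerConfig,
    build_toy_chain,
    dihedral_boost,
    double_well,
    helix_spec,
    sample_biased,
)


@pytest.fixture(scope="session")
def well():
    """Default two-basin potential: ~6 kcal/mol barrier, unequal depths."""
    return double_well()


@pytest.fixture(scope="session")
def gentle_well():
    """Shallow two-basin potential that mixes without a boost."""
    return double_well(depths=(3.0, 2.0), width=40.0)


@pytest.fixture(scope="session")
def biased_run(well):
    """Boosted 5e5-step Metropolis run on the default double well."""
    config = SamplerConfig(n_steps=500_000, seed=1, boost=dihedral_boost(1.0, 4.0))
    return sample_biased(well, config)


@pytest.fixture(scope="session")
def helix_traj():
    """12-residue toy chain jittering inside the right-handed helical basin."""
    spec = helix_spec(12, n_frames=60, phi=-60.0, psi=-38.0, jitter=10.0, seed=7)
    return build_toy_chain(spec)


@pytest.fixture(scope="session")
def ideal_helix_traj():
    return build_toy_chain(helix_spec(18, n_frames=1, phi=-63.0, psi=-43.0))


@pytest.fixture(scope="session")
def extended_traj():
    return build_toy_chain(helix_spec(18, n_frames=1, phi=-157.2, psi=161.9))


def boltzmann_ratio_quadrature(potential, temperature=300.0):
    """Analytic well-occupancy ratio by quadrature on a 1-degree grid.

    Bins are assigned to the basin with the nearest (periodic) center;
    returns Z_basin0 / Z_basin1.
    """
    from amdreweigh import kt, wrap_angle

    grid = np.arange(-180.0, 180.0, 1.0)
    vv = potential.energy(grid[:, None], grid[None, :])
    boltz = np.exp(-vv / kt(temperature))
    dists = []
    for cx, cy in potential.centers:
        dx = wrap_angle(grid[:, None] - cx)
        dy = wrap_angle(grid[None, :] - cy)
        dists.append(np.hypot(dx, dy))
    nearest = np.argmin(np.stack(dists), axis=0)
    z0 = boltz[nearest == 0].sum()
    z1 = boltz[nearest == 1].sum()
    return z0 / z1


def basin_labels(series, potential):
    """Nearest-basin label per frame of a 2D sampler series."""
    from amdreweigh import wrap_angle

    phi, psi = series.phi[:, 0], series.psi[:, 0]
    dists = [
        np.hypot(wrap_angle(phi - cx), wrap_angle(psi - cy))
        for cx, cy in potential.centers
    ]
    return np.argmin(np.stack(dists), axis=0)
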
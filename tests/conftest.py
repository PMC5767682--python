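import numpy as np
import pytest

from condock import fixtures as fx


@pytest.fixture
def hexagon():
    """Regular hexagon of carbons, radius 1.4 Å, in the z=0 plane."""
    return fx.make_symmetric_ligand(6, radius=1.4)


@pytest.fixture
def hexagon_rotated(hexagon):
    return fx.rotate_pose(hexagon, 60.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture
def toy_receptor():
    return fx.make_toy_receptor(n_residues=30, seed=3)


@pytest.fixture
def two_mode_ensemble():
    """Two planted modes, mild noise, no decoys; with ground truth."""
    template = fx.make_symmetric_ligand(6, marker=True)
    spec = fx.FixtureSpec(seed=11, n_modes=2, noise_sd=0.3, decoy_fraction=0.0,
                          poses_per_engine=(12, 8))
    return fx.make_pose_ensemble(spec, template)
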
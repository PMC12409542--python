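import numpy as np
import pandas as pd
import pytest

from confdyn.synthetic import make_two_well_dataset
from confdyn.trajectory import TrajectoryEnsemble

#: One seed for every stochastic fixture in the suite.
SEED = 7


def make_peptide(n_res: int = 3, seed: int = 0) -> TrajectoryEnsemble:
    """Toy peptide: n_res residues x (N, CA, C, O, CB), random static coords."""
    rng = np.random.default_rng(seed)
    names, resids = [], []
    for r in range(1, n_res + 1):
        for name in ("N", "CA", "C", "O", "CB"):
            names.append(name)
            resids.append(r)
    n_atoms = len(names)
    atoms = pd.DataFrame(
        {
            "name": names,
            "resname": ["ALA"] * n_atoms,
            "resid": resids,
            "chain": ["A"] * n_atoms,
            "element": [n[0] for n in names],
        }
    )
    coords = rng.uniform(-10, 10, size=(5, n_atoms, 3))
    return TrajectoryEnsemble(coords=coords, dt=0.1, atoms=atoms)


@pytest.fixture(scope="session")
def toy_peptide() -> TrajectoryEnsemble:
    return make_peptide()


@pytest.fixture(scope="session")
def two_well_data():
    """Default 2-D two-well fixture: latent truth, lifted ensemble, energies."""
    return make_two_well_dataset(seed=SEED, n_latent_steps=50_000, n_frames=1000)


@pytest.fixture(scope="session")
def gaussian_clusters():
    """Two well-separated seeded Gaussian clusters with true labels."""
    rng = np.random.default_rng(SEED)
    a = rng.normal(0.0, 0.5, size=(200, 2))
    b = rng.normal(10.0, 0.5, size=(200, 2))
    x = np.vstack([a, b])
    labels = np.repeat([0, 1], 200)
    return x, labels
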
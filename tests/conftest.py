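import numpy as np
import pytest

import sadsignal as ss


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def default_dataset():
    """A modest simulated SAD data set shared across read-only tests."""
    cfg = ss.SimulationConfig(
        cell=(40, 40, 40, 90, 90, 90),
        d_min=3.0,
        n_ordinary_atoms=300,
        n_substructure_sites=2,
        n_minor_sites=4,
        seed=11,
    )
    return ss.simulate(cfg)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free, minor-free data: observed differences equal the ideal ones."""
    cfg = ss.SimulationConfig(
        cell=(40, 40, 40, 90, 90, 90),
        d_min=3.0,
        n_ordinary_atoms=300,
        n_substructure_sites=2,
        n_minor_sites=0,
        noise_sigma=0.0,
        seed=11,
    )
    return ss.simulate(cfg)


@pytest.fixture
def five_atom_model(rng):
    """Small random P1 model with mixed elements, B factors and occupancies."""
    cell = ss.UnitCell(12, 13, 14, 85, 95, 100)
    atoms = [
        ss.AtomSite("C", tuple(rng.random(3)), 0.9, 12.0),
        ss.AtomSite("N", tuple(rng.random(3)), 1.0, 8.0),
        ss.AtomSite("O", tuple(rng.random(3)), 0.7, 20.0),
        ss.AtomSite("S", tuple(rng.random(3)), 1.0, 15.0),
        ss.AtomSite("SE", tuple(rng.random(3)), 0.8, 25.0),
    ]
    scat = ss.ScatteringModel().register("SE", fprime=-8.0, fdprime=6.0)
    scat.register("S", fdprime=0.56)
    return cell, atoms, scat
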